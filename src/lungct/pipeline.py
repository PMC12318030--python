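"""End-to-end pipeline: simulate -> preprocess -> segment -> extract -> train
-> evaluate, with ablation switches and repeat-run statistics.

The pipeline operates at desk scale on synthetic phantoms.  Its stages are
the library modules; this module only wires them together and collects the
evaluation report (confusion matrix, nine classification metrics, ROC-AUC,
mean test Dice of the segmenter, and mean/median/std/min/max accuracy across
seed-varied repeats).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import classify, deepfeat, evaluate, features, phantom, preprocess, segmentation

log = logging.getLogger("lungct.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

# Luna16-style class balance: 1224 cancer of 2336 instances
_DEFAULT_CANCER_FRACTION = 1224 / 2336


@dataclasses.dataclass
class PipelineConfig:
    n_images: int = 200
    cancer_fraction: float = _DEFAULT_CANCER_FRACTION
    train_fraction: float = 0.8
    seed: int = 0
    repeats: int = 1
    preprocess_enabled: bool = True
    segmentation_enabled: bool = True
    entropy_variant: str = "improved"          # "improved" | "shannon"
    feature_families: tuple[str, ...] = ("lgtrp", "phog", "deep", "entropy")
    phantom: phantom.PhantomSpec = dataclasses.field(
        default_factory=phantom.PhantomSpec)
    filter: preprocess.GaussianFilterParams = dataclasses.field(
        default_factory=preprocess.GaussianFilterParams)
    seg: segmentation.SegModelConfig = dataclasses.field(
        default_factory=segmentation.SegModelConfig)
    classifier: classify.ClassifierConfig = dataclasses.field(
        default_factory=classify.ClassifierConfig)
    deep: deepfeat.DeepFeatConfig = dataclasses.field(
        default_factory=deepfeat.DeepFeatConfig)

    def __post_init__(self):
        if self.entropy_variant not in ("improved", "shannon"):
            raise ValueError("entropy_variant must be 'improved' or 'shannon'")
        unknown = set(self.feature_families) - {"lgtrp", "phog", "deep", "entropy"}
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        if not self.feature_families:
            raise ValueError("at least one feature family is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        nested = {"phantom": phantom.PhantomSpec,
                  "filter": preprocess.GaussianFilterParams,
                  "seg": segmentation.SegModelConfig,
                  "deep": deepfeat.DeepFeatConfig}
        for key, value in raw.items():
            if key in nested:
                if key in ("phantom",) and "lung_ellipse_axes" in value:
                    value["lung_ellipse_axes"] = tuple(value["lung_ellipse_axes"])
                kwargs[key] = nested[key](**value)
            elif key == "classifier":
                iln = classify.ILNConfig(**value.get("iln", {}))
                dm = classify.DMConfig(**value.get("dm", {}))
                kwargs[key] = classify.ClassifierConfig(
                    iln=iln, dm=dm, seed=value.get("seed", 0))
            elif key == "feature_families":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _stage(name: str, seed: int):
    log.info("stage=%s seed=%d t=%.3f", name, seed, time.time())


def _extract_all(seg_images, cfg: PipelineConfig, deep_extractor,
                 entropy_cfg) -> np.ndarray:
    rows = []
    for img in seg_images:
        parts = []
        if "lgtrp" in cfg.feature_families:
            parts.append(features.lgtrp_features(img))
        if "phog" in cfg.feature_families:
            parts.append(features.phog_features(img))
        if "deep" in cfg.feature_families:
            parts.append(deep_extractor(img))
        if "entropy" in cfg.feature_families:
            if cfg.entropy_variant == "improved":
                parts.append([features.improved_entropy(img, entropy_cfg)])
            else:
                parts.append([features.shannon_entropy(img, entropy_cfg)])
        rows.append(np.concatenate([np.asarray(p, dtype=float) for p in parts]))
    return np.stack(rows)


def _single_run(cfg: PipelineConfig) -> dict:
    seed = cfg.seed
    _stage("simulate", seed)
    dataset = phantom.generate_dataset(cfg.n_images, cfg.cancer_fraction,
                                       cfg.phantom, seed)
    labels = dataset.labels
    plan, train_idx, test_idx = evaluate.split_dataset(
        np.arange(len(dataset)), cfg.train_fraction, stratified=True,
        seed=seed, labels=labels)

    _stage("preprocess", seed)
    if cfg.preprocess_enabled:
        images = np.stack([preprocess.adaptive_gaussian_filter(it.image, cfg.filter)
                           for it in dataset])
    else:
        images = dataset.images

    _stage("segment", seed)
    dice_scores = []
    if cfg.segmentation_enabled:
        seg_cfg = dataclasses.replace(cfg.seg, seed=seed,
                                      input_size=cfg.phantom.image_size)
        train_ds = phantom.PhantomDataset(
            items=[phantom.LabeledImage(images[i], dataset.items[i].mask,
                                        dataset.items[i].label)
                   for i in train_idx],
            seed=seed, spec=cfg.phantom)
        model, seg_history = segmentation.train_segmenter(train_ds, seg_cfg)
        masks = np.stack([segmentation.segment(img, model) for img in images])
        seg_images = images * masks
        for i in test_idx:
            dice_scores.append(segmentation.seg_metrics(
                masks[i], dataset.items[i].mask)["dice"])
    else:
        model, seg_history = None, []
        seg_images = images

    _stage("extract", seed)
    deep_cfg = dataclasses.replace(cfg.deep, seed=seed)
    extractor = deepfeat.DeepFeatureExtractor(deep_cfg)
    if "deep" in cfg.feature_families:
        extractor.fit([seg_images[i] for i in train_idx])
    entropy_cfg = features.EntropyConfig()
    feats = _extract_all(seg_images, cfg, extractor, entropy_cfg)

    _stage("train", seed)
    clf_cfg = dataclasses.replace(cfg.classifier, seed=seed)
    iln, dm, histories = classify.train_ensemble(
        seg_images[train_idx], feats[train_idx], labels[train_idx], clf_cfg)

    _stage("evaluate", seed)
    p_iln = iln.predict_proba(seg_images[test_idx])
    p_dm = dm.predict_proba(feats[test_idx])
    fused = np.stack([classify.soft_vote(np.stack([a, b]))[1]
                      for a, b in zip(p_iln, p_dm)])
    preds = np.array([classify.soft_vote(np.stack([a, b]))[0]
                      for a, b in zip(p_iln, p_dm)])
    report = evaluate.confusion_and_metrics(preds, labels[test_idx])
    report.auc = evaluate.roc_auc(fused[:, 1], labels[test_idx])
    return {
        "report": report,
        "plan": plan,
        "dice_test_mean": float(np.mean(dice_scores)) if dice_scores else None,
        "histories": {"segmentation": seg_history, **histories},
        "probabilities": {"iln": p_iln, "dm": p_dm, "fused": fused},
        "test_labels": labels[test_idx],
        "dataset_digest": dataset.digest(),
    }


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None):
    """Execute the full pipeline; repeat with varied seeds if requested.

    Returns ``(EvalReport, artifacts)``; when ``out_dir`` is given the report
    is also written as JSON, CSV and a rendered text table.
    """
    result = _single_run(cfg)
    accuracies = [result["report"].metrics["accuracy"]]
    for r in range(1, cfg.repeats):
        rep_cfg = dataclasses.replace(cfg, seed=cfg.seed + 1000 * r, repeats=1)
        accuracies.append(_single_run(rep_cfg)["report"].metrics["accuracy"])
    report = result["report"]
    report.run_stats = evaluate.run_statistics(accuracies)
    if out_dir is not None:
        write_report(report, result, Path(out_dir))
    return report, result


def write_report(report: evaluate.EvalReport, artifacts: dict,
                 out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict()
    payload["dice_test_mean"] = artifacts.get("dice_test_mean")
    payload["dataset_digest"] = artifacts.get("dataset_digest")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    import csv as _csv
    with open(out_dir / "report.csv", "w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["metric", "value"])
        for k, v in report.metrics.items():
            writer.writerow([k, f"{v:.6f}"])
        writer.writerow(["auc", f"{report.auc:.6f}"])
        for k, v in report.confusion.items():
            writer.writerow([k, v])
    names = {"accuracy": "Accuracy", "precision": "Precision",
             "sensitivity": "Sensitivity", "specificity": "Specificity",
             "f_measure": "F-Measure", "mcc": "MCC", "npv": "NPV",
             "fnr": "FNR", "fpr": "FPR"}
    lines = [f"{names[k]:<12} {v:.4f}" for k, v in report.metrics.items()]
    lines.append(f"{'AUC':<12} {report.auc:.4f}")
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
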