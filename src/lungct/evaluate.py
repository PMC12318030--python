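"""Dataset splitting, confusion-matrix metrics, ROC-AUC and run statistics."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "SplitPlan", "EvalReport", "split_dataset", "confusion_and_metrics",
    "roc_auc", "run_statistics",
]


@dataclasses.dataclass
class SplitPlan:
    train_fraction: float
    n_total: int
    n_train: int
    n_test: int
    stratified: bool
    seed: int


@dataclasses.dataclass
class EvalReport:
    confusion: dict[str, int]
    metrics: dict[str, float]
    auc: float
    run_stats: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out = {"confusion": self.confusion, "metrics": self.metrics,
               "auc": self.auc}
        if self.run_stats is not None:
            out["run_stats"] = self.run_stats
        return out


def split_dataset(ids, train_fraction: float, stratified: bool = True,
                  seed: int = 0, labels=None):
    """Floor-based train/test partition, optionally stratified by label.

    ``n_train = floor(train_fraction * n)``; stratification allocates the
    train quota across classes by largest remainder so the total is exact.
    Returns ``(plan, train_ids, test_ids)``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    ids = np.asarray(ids)
    n = len(ids)
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)
    if stratified and labels is not None:
        labels = np.asarray(labels)
        classes = np.unique(labels)
        quotas = {}
        exact = {c: train_fraction * (labels == c).sum() for c in classes}
        base = {c: int(np.floor(exact[c])) for c in classes}
        short = n_train - sum(base.values())
        remainders = sorted(classes, key=lambda c: exact[c] - base[c],
                            reverse=True)
        for c in classes:
            quotas[c] = base[c]
        for c in remainders[:short]:
            quotas[c] += 1
        train_idx = []
        for c in classes:
            members = np.flatnonzero(labels == c)
            members = members[rng.permutation(len(members))]
            train_idx.extend(members[:quotas[c]])
        train_idx = np.sort(np.array(train_idx, dtype=int))
        mask = np.zeros(n, dtype=bool)
        mask[train_idx] = True
        test_idx = np.flatnonzero(~mask)
    else:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    plan = SplitPlan(train_fraction=train_fraction, n_total=n,
                     n_train=n_train, n_test=n - n_train,
                     stratified=stratified and labels is not None, seed=seed)
    return plan, ids[train_idx], ids[test_idx]


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {name}; reporting 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def confusion_and_metrics(predictions, truths) -> EvalReport:
    """Confusion counts and the nine standard binary metrics.

    Metrics: accuracy, sensitivity (TPR), specificity (TNR), precision,
    F-measure, MCC, NPV, FPR, FNR.  Zero-denominator metrics report 0 with a
    warning so degenerate runs still produce a report.
    """
    pred = np.asarray(predictions, dtype=int)
    truth = np.asarray(truths, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth lengths differ")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    n = tp + tn + fp + fn
    precision = _safe_div(tp, tp + fp, "precision")
    sensitivity = _safe_div(tp, tp + fn, "sensitivity")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    metrics = {
        "accuracy": _safe_div(tp + tn, n, "accuracy"),
        "sensitivity": sensitivity,
        "specificity": _safe_div(tn, tn + fp, "specificity"),
        "precision": precision,
        "f_measure": _safe_div(2 * precision * sensitivity,
                               precision + sensitivity, "f_measure"),
        "mcc": _safe_div(tp * tn - fp * fn, mcc_den, "mcc"),
        "npv": _safe_div(tn, tn + fn, "npv"),
        "fpr": _safe_div(fp, fp + tn, "fpr"),
        "fnr": _safe_div(fn, fn + tp, "fnr"),
    }
    return EvalReport(confusion={"TP": tp, "FP": fp, "TN": tn, "FN": fn},
                      metrics=metrics, auc=float("nan"))


def roc_auc(scores, truths) -> float:
    """Trapezoidal area under the ROC curve (ties count one half)."""
    truths = np.asarray(truths, dtype=int)
    if len(np.unique(truths)) < 2:
        raise ValueError("ROC-AUC requires both classes in the truth labels")
    return float(roc_auc_score(truths, np.asarray(scores, dtype=float)))


def run_statistics(accuracies) -> dict[str, float]:
    """Mean / median / std / min / max across repeated runs."""
    acc = np.asarray(accuracies, dtype=float)
    return {"mean": float(acc.mean()), "median": float(np.median(acc)),
            "std": float(acc.std()), "min": float(acc.min()),
            "max": float(acc.max())}
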