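"""Synthetic lung-slice phantoms with ground-truth masks and labels.

Each phantom is a 2-D grayscale image (float intensities in [0, 1]) showing a
darker elliptical lung field on a brighter background, optionally containing
one or more bright nodule blobs with smooth Gaussian-profile edges.  The blob
support defines the ground-truth mask; an image is labelled cancerous (1)
exactly when its mask contains at least one foreground pixel.  Everything is
driven by a single integer seed, so a dataset regenerates bit-identically
from ``(spec, seed)``.

The generator stands in, at desk scale, for thoracic CT slices: a class-
balanced collection of slices with and without nodules, plus the masks a
segmenter should recover.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec", "LabeledImage", "PhantomDataset",
    "generate_phantom", "add_noise", "generate_dataset", "save_dataset",
]


class ConfigurationError(ValueError):
    """Raised when a spec or parameter set is internally inconsistent."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise description of one phantom family.

    ``lung_ellipse_axes`` are semi-axis lengths as fractions of the image
    side; nodule radii are in pixels; intensities are relative on [0, 1].
    """

    image_size: int = 64
    lung_ellipse_axes: tuple[float, float] = (0.32, 0.40)
    nodule_count_range: tuple[int, int] = (1, 3)
    nodule_radius_range: tuple[float, float] = (3.0, 6.0)
    nodule_intensity: float = 0.85
    background_intensity: float = 0.65
    lung_intensity: float = 0.18
    noise_model: str = "gaussian"
    noise_sigma: float = 0.03

    def __post_init__(self):
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        lo, hi = self.nodule_radius_range
        if not (0 < lo <= hi < self.image_size / 4):
            raise ConfigurationError(
                "nodule radii must be positive and below image_size/4")
        if not (0 <= self.nodule_count_range[0] <= self.nodule_count_range[1]):
            raise ConfigurationError("invalid nodule_count_range")
        for name in ("nodule_intensity", "background_intensity",
                     "lung_intensity", "noise_sigma"):
            v = getattr(self, name)
            if name != "noise_sigma" and not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "speckle"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")


@dataclasses.dataclass
class LabeledImage:
    image: np.ndarray
    mask: np.ndarray
    label: int

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask dimensions differ")


@dataclasses.dataclass
class PhantomDataset:
    items: list[LabeledImage]
    seed: int
    spec: PhantomSpec

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def images(self) -> np.ndarray:
        return np.stack([it.image for it in self.items])

    @property
    def masks(self) -> np.ndarray:
        return np.stack([it.mask for it in self.items])

    @property
    def labels(self) -> np.ndarray:
        return np.array([it.label for it in self.items], dtype=int)

    def digest(self) -> str:
        h = hashlib.sha256()
        for it in self.items:
            h.update(it.image.tobytes())
            h.update(it.mask.tobytes())
            h.update(bytes([it.label]))
        return h.hexdigest()


def _lung_field(size: int, axes: tuple[float, float]) -> np.ndarray:
    """Boolean mask of the two lung lobes (a pair of offset ellipses)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = size / 2
    a, b = axes[0] * size / 2, axes[1] * size
    field = np.zeros((size, size), dtype=bool)
    for cx in (size * 0.30, size * 0.70):
        field |= ((xx - cx) / a) ** 2 + ((yy - cy) / (b / 2)) ** 2 <= 1.0
    return field


def generate_phantom(spec: PhantomSpec, seed: int,
                     with_nodules: bool | None = None) -> LabeledImage:
    """Draw one phantom slice.

    ``with_nodules`` forces the class: True draws at least one nodule, False
    none; None draws a count uniformly from ``spec.nodule_count_range``.
    """
    rng = np.random.default_rng(seed)
    size = spec.image_size
    img = np.full((size, size), spec.background_intensity)
    lung = _lung_field(size, spec.lung_ellipse_axes)
    img[lung] = spec.lung_intensity

    lo, hi = spec.nodule_count_range
    if with_nodules is True:
        n_nodules = int(rng.integers(max(lo, 1), hi + 1)) if hi >= 1 else 0
    elif with_nodules is False:
        n_nodules = 0
    else:
        n_nodules = int(rng.integers(lo, hi + 1))

    mask = np.zeros((size, size), dtype=np.uint8)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    for _ in range(n_nodules):
        r = rng.uniform(*spec.nodule_radius_range)
        # sample the centre from the lung field eroded by r, so the whole
        # nodule sits inside the lung; fall back to the full field if the
        # erosion empties it
        rad = int(np.ceil(r))
        struct = (np.hypot(*np.mgrid[-rad:rad + 1, -rad:rad + 1]) <= r)
        eroded = ndimage.binary_erosion(lung, structure=struct)
        ys, xs = np.nonzero(eroded if eroded.any() else lung)
        idx = rng.integers(len(ys))
        cy, cx = float(ys[idx]), float(xs[idx])
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        # Gaussian-profile blob: flat bright core of radius r, smooth skirt
        profile = np.exp(-0.5 * d2 / (r / 2) ** 2) / np.exp(-2.0)
        blob = np.minimum(profile, 1.0)
        inside = (d2 <= r * r) & lung
        mask[inside] = 1
        img = np.where(lung, np.maximum(img, spec.nodule_intensity * blob), img)

    img = add_noise(img, spec.noise_model, spec.noise_sigma,
                    seed=int(rng.integers(2 ** 31)))
    label = int(mask.any())
    return LabeledImage(image=img, mask=mask, label=label)


def add_noise(image: np.ndarray, model: str, sigma: float, seed: int) -> np.ndarray:
    """Add seeded noise and clip back to the [0, 1] intensity contract."""
    if sigma < 0:
        raise ConfigurationError("sigma must be >= 0")
    if model not in ("gaussian", "speckle"):
        raise ConfigurationError(f"unknown noise model {model!r}")
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=image.shape)
    if model == "speckle":
        noisy = image * (1.0 + noise)
    else:
        noisy = image + noise
    return np.clip(noisy, 0.0, 1.0)


def generate_dataset(n: int, cancer_fraction: float, spec: PhantomSpec,
                     seed: int) -> PhantomDataset:
    """Generate ``n`` phantoms with exactly round(n*cancer_fraction) positives."""
    if n <= 0:
        raise ConfigurationError("n must be positive")
    if not 0.0 <= cancer_fraction <= 1.0:
        raise ConfigurationError("cancer_fraction must lie in [0, 1]")
    n_cancer = int(round(n * cancer_fraction))
    if n_cancer > 0 and spec.nodule_count_range[1] < 1:
        raise ConfigurationError(
            "cancer_fraction > 0 requires nodule_count_range to allow nodules")
    rng = np.random.default_rng(seed)
    flags = np.array([True] * n_cancer + [False] * (n - n_cancer))
    rng.shuffle(flags)
    items = []
    for flag in flags:
        items.append(generate_phantom(spec, seed=int(rng.integers(2 ** 31)),
                                      with_nodules=bool(flag)))
    return PhantomDataset(items=items, seed=seed, spec=spec)


def save_dataset(dataset: PhantomDataset, out_dir: str | Path) -> Path:
    """Write images/masks as 8-bit PNG plus a CSV manifest; return manifest path."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "mask_path", "label", "seed"])
        for i, item in enumerate(dataset.items):
            img_path = out / f"img_{i:04d}.png"
            mask_path = out / f"mask_{i:04d}.png"
            iio.imwrite(img_path, (item.image * 255).round().astype(np.uint8))
            iio.imwrite(mask_path, (item.mask * 255).astype(np.uint8))
            writer.writerow([img_path.name, mask_path.name, item.label,
                             dataset.seed])
    return manifest
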