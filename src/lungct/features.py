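"""Hybrid 201-dimensional feature extraction from segmented lung images.

Four feature families are concatenated, in order:

====================  ======  =============================================
segment               length  description
====================  ======  =============================================
``lgtrp``             50      Local Gabor Transitional Pattern: maximum
                              Gabor magnitude over orientations, two-radius
                              directional transition codes, regional
                              histograms (whole image + 2x2 grid, 10 bins).
``phog``              50      Pyramid of Histograms of Oriented Gradients:
                              Sobel gradients, unsigned orientations in
                              [0, 180), 10 bins at pyramid levels {0, 1}.
``deep``              100     Convolutional-encoder activations projected
                              by PCA (see :mod:`lungct.deepfeat`).
``ien``               1       Improved entropy: a data-weighted blend of
                              Shannon entropy and normalized first-order
                              entropy.
====================  ======  =============================================

The improved entropy is ``IEn = W*En + (1-W)*NEn`` with ``W = 2*(1 -
1/(1+exp(En)))``, a reverse-sigmoid weight of the Shannon entropy itself.
Note that W > 1 whenever En > 0, so the normalized-entropy term enters with
a negative coefficient; the formula is applied exactly as defined.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.filters import gabor_kernel

__all__ = [
    "GaborParams", "LGTrPConfig", "PHOGConfig", "EntropyConfig",
    "FeatureVector201", "gabor_response", "ltp_code_map", "lgtrp_features",
    "gradient_field", "phog_features", "shannon_entropy", "entropy_weight",
    "normalized_entropy", "improved_entropy", "extract_feature_vector",
]


@dataclasses.dataclass(frozen=True)
class GaborParams:
    wavelength: float = 4.0
    orientations: tuple[float, ...] = tuple(np.deg2rad([0, 45, 90, 135]))
    envelope_sigma: float = 2.0
    phase: float = 0.0
    aspect_ratio: float = 1.0

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if len(self.orientations) < 1:
            raise ValueError("need at least one orientation")


@dataclasses.dataclass(frozen=True)
class LGTrPConfig:
    directions: int = 8
    r1: float = 1.0
    r2: float = 2.0
    grid: int = 2            # regions = grid*grid + whole image
    bins: int = 10

    def __post_init__(self):
        if not self.r1 < self.r2:
            raise ValueError("need r1 < r2")
        if self.directions < 2:
            raise ValueError("need at least two directions")

    @property
    def n_regions(self) -> int:
        return self.grid * self.grid + 1

    @property
    def length(self) -> int:
        return self.n_regions * self.bins


@dataclasses.dataclass(frozen=True)
class PHOGConfig:
    levels: tuple[int, ...] = (0, 1)
    bins: int = 10
    angle_range: str = "unsigned_180"

    def __post_init__(self):
        if self.angle_range not in ("unsigned_180", "signed_360"):
            raise ValueError(f"unknown angle_range {self.angle_range!r}")

    @property
    def length(self) -> int:
        return self.bins * sum(4 ** lv for lv in self.levels)


@dataclasses.dataclass(frozen=True)
class EntropyConfig:
    bits_per_pixel: int = 8
    log_base: int = 2

    def __post_init__(self):
        if self.bits_per_pixel < 1:
            raise ValueError("bits_per_pixel must be >= 1")


@dataclasses.dataclass
class FeatureVector201:
    lgtrp: np.ndarray
    phog: np.ndarray
    deep: np.ndarray
    ien: float

    def __post_init__(self):
        for name, expect in (("lgtrp", 50), ("phog", 50), ("deep", 100)):
            got = len(getattr(self, name))
            if got != expect:
                raise ValueError(f"{name} segment has length {got}, expected {expect}")

    @property
    def layout(self) -> dict[str, tuple[int, int]]:
        return {"lgtrp": (0, 50), "phog": (50, 100), "deep": (100, 200),
                "ien": (200, 201)}

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.lgtrp, self.phog, self.deep, [self.ien]])


# -- Gabor ------------------------------------------------------------------

def gabor_response(image: np.ndarray, params: GaborParams) -> np.ndarray:
    """Maximum complex-Gabor magnitude over orientations.

    Kernels are made zero-mean (DC-free), so a constant intensity offset
    leaves the response unchanged.
    """
    image = np.asarray(image, dtype=float)
    best = np.zeros_like(image)
    for theta in params.orientations:
        k = gabor_kernel(frequency=1.0 / params.wavelength, theta=theta,
                         sigma_x=params.envelope_sigma,
                         sigma_y=params.envelope_sigma / params.aspect_ratio,
                         offset=params.phase)
        k = k - k.mean()
        re = ndimage.convolve(image, np.real(k), mode="reflect")
        im = ndimage.convolve(image, np.imag(k), mode="reflect")
        best = np.maximum(best, np.hypot(re, im))
    return best


# -- LGTrP ------------------------------------------------------------------

def _bilinear(image: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(image, [ys, xs], order=1, mode="nearest")


def ltp_code_map(image: np.ndarray, config: LGTrPConfig) -> np.ndarray:
    """Two-radius directional transition codes in [0, 2^L).

    For each direction l, the bit is set when the intensity rises strictly
    outward at both radii: step(G_l1 - G_c) * step(G_l2 - G_c) with
    step(d) = 1 iff d > 0 (ties break to 0).  Border pixels within
    ceil(r2) of the edge are excluded; off-grid neighbours are sampled with
    bilinear interpolation.
    """
    image = np.asarray(image, dtype=float)
    margin = int(np.ceil(config.r2))
    h, w = image.shape
    if h <= 2 * margin + 1 or w <= 2 * margin + 1:
        raise ValueError("image too small for the requested radii")
    yy, xx = np.mgrid[margin:h - margin, margin:w - margin].astype(float)
    center = image[margin:h - margin, margin:w - margin]
    codes = np.zeros(center.shape, dtype=np.int64)
    for l in range(config.directions):
        angle = 2.0 * np.pi * l / config.directions
        dy, dx = np.sin(angle), np.cos(angle)
        g1 = _bilinear(image, yy + config.r1 * dy, xx + config.r1 * dx)
        g2 = _bilinear(image, yy + config.r2 * dy, xx + config.r2 * dx)
        bit = (g1 > center) & (g2 > center)
        codes |= bit.astype(np.int64) << l
    return codes


def _region_histograms(values: np.ndarray, grid: int, bins: int,
                       value_range: tuple[float, float]) -> np.ndarray:
    """Whole-image + grid x grid regional histograms, each L1-normalised."""
    blocks = [values]
    h, w = values.shape
    ys = np.linspace(0, h, grid + 1).astype(int)
    xs = np.linspace(0, w, grid + 1).astype(int)
    for i in range(grid):
        for j in range(grid):
            blocks.append(values[ys[i]:ys[i + 1], xs[j]:xs[j + 1]])
    out = []
    for block in blocks:
        hist, _ = np.histogram(block, bins=bins, range=value_range)
        total = hist.sum()
        out.append(hist / total if total > 0 else np.zeros(bins))
    return np.concatenate(out)


def lgtrp_features(seg_image: np.ndarray, gabor: GaborParams | None = None,
                   config: LGTrPConfig | None = None) -> np.ndarray:
    """Gabor response -> transition code map -> 50 regional histogram values."""
    gabor = gabor or GaborParams()
    config = config or LGTrPConfig()
    response = gabor_response(seg_image, gabor)
    codes = ltp_code_map(response, config)
    return _region_histograms(codes.astype(float), config.grid, config.bins,
                              (0.0, float(2 ** config.directions)))


# -- PHOG -------------------------------------------------------------------

@dataclasses.dataclass
class GradientField:
    magnitude: np.ndarray
    orientation: np.ndarray


def gradient_field(image: np.ndarray,
                   angle_range: str = "unsigned_180") -> GradientField:
    """Sobel gradient magnitude and full-quadrant orientation."""
    image = np.asarray(image, dtype=float)
    if min(image.shape) < 3:
        raise ValueError("image must be at least 3x3")
    gp = ndimage.sobel(image, axis=1, mode="reflect")   # d/dx
    gq = ndimage.sobel(image, axis=0, mode="reflect")   # d/dy
    magnitude = np.hypot(gp, gq)
    orientation = np.arctan2(gq, gp)
    if angle_range == "unsigned_180":
        orientation = np.mod(orientation, np.pi)
    else:
        orientation = np.mod(orientation, 2.0 * np.pi)
    return GradientField(magnitude=magnitude, orientation=orientation)


def phog_features(seg_image: np.ndarray,
                  config: PHOGConfig | None = None) -> np.ndarray:
    """Magnitude-weighted orientation histograms over a spatial pyramid."""
    config = config or PHOGConfig()
    image = np.asarray(seg_image, dtype=float)
    cells_max = 2 ** max(config.levels)
    if image.shape[0] % cells_max or image.shape[1] % cells_max:
        raise ValueError(
            f"image dims {image.shape} not divisible by 2^max(level) = {cells_max}")
    field = gradient_field(image, config.angle_range)
    top = np.pi if config.angle_range == "unsigned_180" else 2.0 * np.pi
    parts = []
    for level in config.levels:
        n = 2 ** level
        hs = np.linspace(0, image.shape[0], n + 1).astype(int)
        ws = np.linspace(0, image.shape[1], n + 1).astype(int)
        for i in range(n):
            for j in range(n):
                ori = field.orientation[hs[i]:hs[i + 1], ws[j]:ws[j + 1]]
                mag = field.magnitude[hs[i]:hs[i + 1], ws[j]:ws[j + 1]]
                hist, _ = np.histogram(ori, bins=config.bins, range=(0.0, top),
                                       weights=mag)
                parts.append(hist)
    vec = np.concatenate(parts)
    total = vec.sum()
    return vec / total if total > 0 else vec


# -- entropy ----------------------------------------------------------------

def _quantize(image: np.ndarray, bits: int) -> np.ndarray:
    """Scale [0, 1] intensities to [0, 2^bits - 1] and floor."""
    levels = 2 ** bits - 1
    return np.floor(np.clip(np.asarray(image, dtype=float), 0, 1)
                    * levels).astype(int)


def shannon_entropy(image: np.ndarray,
                    config: EntropyConfig | None = None) -> float:
    """Shannon entropy (bits) over the 2^t quantized gray levels."""
    config = config or EntropyConfig()
    q = _quantize(image, config.bits_per_pixel)
    counts = np.bincount(q.ravel(), minlength=2 ** config.bits_per_pixel)
    p = counts[counts > 0] / q.size
    return float(-(p * np.log2(p)).sum())


def entropy_weight(en: float) -> float:
    """Reverse-sigmoid weight W = 2 * (1 - 1/(1 + exp(En)))."""
    return 2.0 * (1.0 - 1.0 / (1.0 + np.exp(en)))


def normalized_entropy(image: np.ndarray, bits: int = 8) -> float:
    """First-order entropy over the distinct values present / log2(N_m).

    A constant image (single distinct value) returns 0 by convention.
    """
    q = _quantize(image, bits)
    _, counts = np.unique(q, return_counts=True)
    n_m = len(counts)
    if n_m <= 1:
        return 0.0
    p = counts / counts.sum()
    en1 = float(-(p * np.log2(p)).sum())
    return en1 / float(np.log2(n_m))


def improved_entropy(image: np.ndarray,
                     config: EntropyConfig | None = None) -> float:
    """IEn = W*En + (1 - W)*NEn with the reverse-sigmoid weight W(En)."""
    config = config or EntropyConfig()
    en = shannon_entropy(image, config)
    nen = normalized_entropy(image, config.bits_per_pixel)
    w = entropy_weight(en)
    return w * en + (1.0 - w) * nen


# -- assembly ---------------------------------------------------------------

def extract_feature_vector(seg_image: np.ndarray, deep_extractor,
                           gabor: GaborParams | None = None,
                           lgtrp_config: LGTrPConfig | None = None,
                           phog_config: PHOGConfig | None = None,
                           entropy_config: EntropyConfig | None = None) -> FeatureVector201:
    """Ordered concatenation [LGTrP(50) | PHOG(50) | Deep(100) | IEn(1)].

    ``deep_extractor`` is a fitted :class:`lungct.deepfeat.DeepFeatureExtractor`
    (or any callable mapping an image to 100 values).
    """
    lg = lgtrp_features(seg_image, gabor, lgtrp_config)
    ph = phog_features(seg_image, phog_config)
    deep = np.asarray(deep_extractor(seg_image), dtype=float)
    ien = improved_entropy(seg_image, entropy_config)
    return FeatureVector201(lgtrp=lg, phog=ph, deep=deep, ien=ien)
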