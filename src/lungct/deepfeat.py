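"""Deep convolutional features with PCA projection to 100 dimensions.

Two seed-initialised convolutional encoders process the (3-channel
replicated, resized) segmented image: an AlexNet-style plain stack tapped at
a 4096-wide fully-connected layer, and a ResNet-style residual stack tapped
at a 2048-wide pooled layer.  The 6144 concatenated raw activations from the
training images fit one joint PCA whose first 100 principal components give
the ``deep`` feature segment.  The encoders are forward-only: with fixed
random weights they act as seeded random convolutional projections, which
keeps extraction fully deterministic and self-contained while preserving the
tap widths and the PCA reduction of the original design.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.transform import resize
from sklearn.decomposition import PCA

from . import nn
from .nn import Tensor

__all__ = ["DeepFeatConfig", "DeepFeatureExtractor", "fit_pca"]


@dataclasses.dataclass(frozen=True)
class DeepFeatConfig:
    backbones: tuple[str, ...] = ("alexnet", "resnet50")
    pretrained: bool = False
    pca_components: int = 100
    input_size: int = 64
    seed: int = 0

    def __post_init__(self):
        for b in self.backbones:
            if b not in ("alexnet", "resnet50"):
                raise ValueError(f"unknown backbone {b!r}")
        if self.pretrained:
            raise ValueError(
                "pretrained weights are not available; use pretrained=False "
                "(seed-initialised encoders)")


def fit_pca(raw_features: np.ndarray, components: int = 100) -> PCA:
    """Fit a mean-centred orthonormal PCA basis (deterministic full SVD)."""
    raw_features = np.asarray(raw_features, dtype=float)
    if raw_features.shape[0] < components:
        raise ValueError(
            f"need at least {components} samples to fit {components} "
            f"components, got {raw_features.shape[0]}")
    pca = PCA(n_components=components, svd_solver="full")
    pca.fit(raw_features)
    return pca


def _adaptive_avg_pool(x: np.ndarray, out_size: int) -> np.ndarray:
    """(C, H, W) -> (C, out, out) average pooling; H, W divisible by out."""
    c, h, w = x.shape
    kh, kw = h // out_size, w // out_size
    x = x[:, :kh * out_size, :kw * out_size]
    return x.reshape(c, out_size, kh, out_size, kw).mean(axis=(2, 4))


class _AlexNetStyle:
    """Plain conv stack tapped at a 4096-wide fully-connected layer."""

    tap_width = 4096

    def __init__(self, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(rng, 3, 16, 5, padding=2)
        self.conv2 = nn.Conv2d(rng, 16, 32, 3)
        self.conv3 = nn.Conv2d(rng, 32, 32, 3)
        self.fc = rng.normal(0.0, 1.0 / np.sqrt(2048), size=(2048, 4096))

    def __call__(self, x: Tensor) -> np.ndarray:
        x = self.conv1(x).relu()
        x = nn.max_pool2d(x, 2)
        x = self.conv2(x).relu()
        x = nn.max_pool2d(x, 2)
        x = self.conv3(x).relu()
        pooled = _adaptive_avg_pool(x.data[0], 8).ravel()
        return np.maximum(pooled @ self.fc, 0.0)


class _ResNetStyle:
    """Residual conv stack tapped at a 2048-wide pooled layer."""

    tap_width = 2048

    def __init__(self, rng: np.random.Generator):
        self.conv0 = nn.Conv2d(rng, 3, 16, 3)
        self.b1a = nn.Conv2d(rng, 16, 16, 3)
        self.b1b = nn.Conv2d(rng, 16, 16, 3)
        self.b2a = nn.Conv2d(rng, 16, 32, 3)
        self.b2b = nn.Conv2d(rng, 32, 32, 3)
        self.skip2 = nn.Conv2d(rng, 16, 32, 1, padding=0)

    def __call__(self, x: Tensor) -> np.ndarray:
        x = self.conv0(x).relu()
        x = (self.b1b(self.b1a(x).relu()) + x).relu()
        x = nn.max_pool2d(x, 2)
        x = (self.b2b(self.b2a(x).relu()) + self.skip2(x)).relu()
        x = nn.max_pool2d(x, 2)
        return _adaptive_avg_pool(x.data[0], 8).ravel()


_ENCODERS = {"alexnet": _AlexNetStyle, "resnet50": _ResNetStyle}


class DeepFeatureExtractor:
    """Raw encoder taps -> joint PCA -> 100-dimensional deep features."""

    def __init__(self, config: DeepFeatConfig | None = None):
        self.config = config or DeepFeatConfig()
        rng = np.random.default_rng(self.config.seed)
        self.encoders = [_ENCODERS[name](rng) for name in self.config.backbones]
        self.pca: PCA | None = None

    @property
    def raw_width(self) -> int:
        return sum(e.tap_width for e in self.encoders)

    def encode_raw(self, image: np.ndarray) -> np.ndarray:
        """Resize, replicate to 3 channels, concatenate the encoder taps."""
        image = np.asarray(image, dtype=float)
        size = self.config.input_size
        if image.shape != (size, size):
            image = resize(image, (size, size), anti_aliasing=True)
        x = Tensor(np.repeat(image[None, None], 3, axis=1))
        return np.concatenate([enc(x) for enc in self.encoders])

    def fit(self, images: list[np.ndarray] | np.ndarray) -> "DeepFeatureExtractor":
        raw = np.stack([self.encode_raw(img) for img in images])
        self.pca = fit_pca(raw, self.config.pca_components)
        return self

    def __call__(self, image: np.ndarray) -> np.ndarray:
        if self.pca is None:
            raise RuntimeError("DeepFeatureExtractor is not fitted; call fit()")
        raw = self.encode_raw(image)
        return self.pca.transform(raw[None])[0]
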