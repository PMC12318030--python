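"""Soft-voting ensemble of an improved-LeNet transfer classifier and a
DeepMaxout classifier.

``ILNTL`` routes the segmented image through a frozen VGG-style
convolutional trunk, Gaussian-normalises the trunk activations around their
Lehmer mean (``N_Z = (((X - mu_L)/(3 sigma)) + 1)/2`` with ``mu_L = sum x^Q
/ sum x^(Q-1)``, Q = 2), then applies a depthwise separable convolution,
max pooling, min pooling, and two dropout-regularised dense(128, relu)
layers before a 2-way softmax.  Because the trunk is frozen its activations
are precomputed once per dataset, and only the head is trained.

``DeepMaxout`` consumes the 201-dimensional hybrid feature vector as a 1-D
sequence: convolution, batch normalisation, k=2 pooling, then a maxout dense
block (elementwise max over k affine pieces) and a 2-way softmax.

``soft_vote`` fuses the two probability rows with weights (0.5, 0.5):
``Y = argmax_i sum_j w_j p_ij``; exact ties resolve to the non-cancer
class 0.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "NormalizationParams", "ClassifierConfig", "lehmer_mean",
    "GaussianNormalizer", "gaussian_normalize", "min_pool", "maxout",
    "ILNTL", "DeepMaxout", "build_iln_tl", "build_deep_maxout",
    "train_ensemble", "soft_vote",
]


# -- normalisation ----------------------------------------------------------

def lehmer_mean(values: np.ndarray, q: float = 2.0) -> float:
    """Lehmer mean (sum x^Q)/(sum x^(Q-1)); Q=1 is the arithmetic mean.

    If the denominator is degenerate (|sum x^(Q-1)| < 1e-8) the arithmetic
    mean is returned with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    den = float((values ** (q - 1.0)).sum())
    if abs(den) < 1e-8:
        warnings.warn("degenerate Lehmer denominator; falling back to "
                      "arithmetic mean", RuntimeWarning, stacklevel=2)
        return float(values.mean())
    return float((values ** q).sum()) / den


@dataclasses.dataclass
class NormalizationParams:
    lehmer_q: float = 2.0
    mu_l: np.ndarray | None = None
    sigma: np.ndarray | None = None
    clip: bool = True

    @property
    def fitted(self) -> bool:
        return self.mu_l is not None and self.sigma is not None


class GaussianNormalizer:
    """Per-feature Lehmer-mean Gaussian normalisation, fitted on training data."""

    def __init__(self, q: float = 2.0, clip: bool = True, eps: float = 1e-8):
        self.params = NormalizationParams(lehmer_q=q, clip=clip)
        self.eps = eps

    def fit(self, x: np.ndarray) -> "GaussianNormalizer":
        x = np.asarray(x, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.array([lehmer_mean(col, self.params.lehmer_q) for col in x.T])
        self.params.mu_l = mu
        self.params.sigma = np.maximum(x.std(axis=0), self.eps)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return gaussian_normalize(x, self.params)

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)


def gaussian_normalize(x: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """N_Z = (((X - mu_L) / (3 sigma)) + 1) / 2, optionally clipped to [0, 1]."""
    if not params.fitted:
        raise RuntimeError("normalization parameters are not fitted")
    x = np.asarray(x, dtype=float)
    out = ((x - params.mu_l) / (3.0 * params.sigma) + 1.0) / 2.0
    return np.clip(out, 0.0, 1.0) if params.clip else out


# -- small public ops -------------------------------------------------------

def min_pool(grid: np.ndarray, k: int) -> np.ndarray:
    """Per-window minimum over non-overlapping k x k windows."""
    grid = np.asarray(grid, dtype=float)
    h, w = grid.shape
    if h % k or w % k:
        raise ValueError(f"grid dims {(h, w)} not divisible by {k}")
    return grid.reshape(h // k, k, w // k, k).min(axis=(1, 3))


def maxout(x: np.ndarray, weights: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Elementwise maximum over k affine pieces w_k @ x + b_k.

    ``weights`` has shape (k, out, in) and ``biases`` (k, out).
    """
    x = np.asarray(x, dtype=float)
    if weights.shape[0] < 2:
        raise ValueError("maxout needs at least two pieces")
    pieces = np.einsum("koi,i->ko", weights, x) + biases
    return pieces.max(axis=0)


# -- configs ----------------------------------------------------------------

@dataclasses.dataclass
class ILNConfig:
    hidden_neurons: int = 128
    activation: str = "relu"
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 64
    validation_split: float = 0.2
    epochs: int = 50
    dw_kernel: int = 5
    dropout: float = 0.2
    trunk_channels: tuple[int, int] = (8, 16)
    fine_tune: bool = False


@dataclasses.dataclass
class DMConfig:
    batch_size: int = 32
    learning_rate: float = 0.01
    pool_k: int = 2
    epochs: int = 50
    maxout_pieces: int = 3
    conv_channels: int = 16
    conv_kernel: int = 3
    maxout_units: int = 64


@dataclasses.dataclass
class ClassifierConfig:
    iln: ILNConfig = dataclasses.field(default_factory=ILNConfig)
    dm: DMConfig = dataclasses.field(default_factory=DMConfig)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.iln.validation_split < 1:
            raise ValueError("validation_split must lie in (0, 1)")


# -- ILN-TL -----------------------------------------------------------------

class _MiniVGGTrunk(nn.Module):
    """Compact VGG-style conv trunk (3x3 convs, relu, two max-pool stages)."""

    def __init__(self, rng, channels: tuple[int, int]):
        super().__init__()
        c1, c2 = channels
        self.conv1a = nn.Conv2d(rng, 1, c1, 3)
        self.conv1b = nn.Conv2d(rng, c1, c1, 3)
        self.conv2a = nn.Conv2d(rng, c1, c2, 3)
        self.conv2b = nn.Conv2d(rng, c2, c2, 3)
        self.out_channels = c2

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv1b(self.conv1a(x).relu()).relu()
        x = nn.max_pool2d(x, 2)
        x = self.conv2b(self.conv2a(x).relu()).relu()
        return nn.max_pool2d(x, 2)


class ILNTL(nn.Module):
    """Improved-LeNet head on a frozen VGG-style trunk with transfer of its
    fixed representations; trained on segmented images."""

    def __init__(self, config: ClassifierConfig, input_size: int = 64):
        super().__init__()
        cfg = config.iln
        self.config = config
        self.input_size = input_size
        rng = np.random.default_rng(config.seed)
        self.trunk = _MiniVGGTrunk(rng, cfg.trunk_channels)
        c = self.trunk.out_channels
        self.normalizer = GaussianNormalizer()
        self.dwsep = nn.DepthwiseSeparableConv2d(rng, c, c, cfg.dw_kernel)
        feat_size = input_size // 4 // 4          # two trunk pools, max+min pool
        flat = c * feat_size * feat_size
        self.fc1 = nn.Dense(rng, flat, cfg.hidden_neurons)
        self.drop1 = nn.Dropout(cfg.dropout, np.random.default_rng(config.seed + 11))
        self.fc2 = nn.Dense(rng, cfg.hidden_neurons, cfg.hidden_neurons)
        self.drop2 = nn.Dropout(cfg.dropout, np.random.default_rng(config.seed + 12))
        self.out = nn.Dense(rng, cfg.hidden_neurons, 2)

    # trunk handling -------------------------------------------------------

    def trunk_features(self, images: np.ndarray) -> np.ndarray:
        """Frozen-trunk activations, (N, C, H/4, W/4), no gradients."""
        x = Tensor(np.asarray(images, dtype=float)[:, None])
        return self.trunk(x).data

    def trunk_digest(self) -> str:
        h = hashlib.sha256()
        for p in self.trunk.parameters():
            h.update(p.data.tobytes())
        return h.hexdigest()

    def head_parameters(self) -> list[nn.Parameter]:
        trunk = set(id(p) for p in self.trunk.parameters())
        return [p for p in self.parameters() if id(p) not in trunk]

    # forward --------------------------------------------------------------

    def head_logits(self, feats: Tensor) -> Tensor:
        x = self.dwsep(feats).relu()
        x = nn.max_pool2d(x, 2)
        x = nn.min_pool2d(x, 2)
        n = x.shape[0]
        x = x.reshape(n, -1)
        x = self.drop1(self.fc1(x).relu())
        x = self.drop2(self.fc2(x).relu())
        return self.out(x)

    def _normalized_features(self, images: np.ndarray) -> np.ndarray:
        feats = self.trunk_features(images)
        flat = feats.reshape(feats.shape[0], -1)
        return self.normalizer.transform(flat).reshape(feats.shape)

    def fit(self, images: np.ndarray, labels: np.ndarray):
        """Train the head (Table-style regimen: adam, categorical CE)."""
        cfg = self.config.iln
        feats = self.trunk_features(images)
        flat = feats.reshape(feats.shape[0], -1)
        self.normalizer.fit(flat)
        normed = self.normalizer.transform(flat).reshape(feats.shape)
        params = self.head_parameters()
        if cfg.fine_tune:
            params = self.parameters()
        opt = nn.Adam(params, lr=cfg.learning_rate)
        rng = np.random.default_rng(self.config.seed + 21)
        n = len(images)
        n_val = int(round(cfg.validation_split * n))
        order = rng.permutation(n)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        history = {"loss": [], "val_loss": [], "n_val": n_val}
        for _ in range(cfg.epochs):
            perm = rng.permutation(len(tr_idx))
            epoch_loss = 0.0
            for start in range(0, len(tr_idx), cfg.batch_size):
                idx = tr_idx[perm[start:start + cfg.batch_size]]
                opt.zero_grad()
                logits = self.head_logits(Tensor(normed[idx]))
                loss = nn.cross_entropy(logits, labels[idx])
                loss.backward()
                opt.step()
                epoch_loss += loss.item() * len(idx)
            history["loss"].append(epoch_loss / max(len(tr_idx), 1))
            if n_val:
                self.eval()
                vl = nn.cross_entropy(
                    self.head_logits(Tensor(normed[val_idx])), labels[val_idx])
                history["val_loss"].append(vl.item())
                self.train()
        return history

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        self.eval()
        normed = self._normalized_features(np.asarray(images, dtype=float))
        probs = nn.softmax(self.head_logits(Tensor(normed))).data
        self.train()
        return probs


def build_iln_tl(config: ClassifierConfig | None = None,
                 input_size: int = 64) -> ILNTL:
    return ILNTL(config or ClassifierConfig(), input_size)


# -- DeepMaxout -------------------------------------------------------------

class DeepMaxout(nn.Module):
    """1-D conv + batch-norm + pool + maxout classifier over feature vectors."""

    def __init__(self, config: ClassifierConfig, input_dim: int = 201):
        super().__init__()
        cfg = config.dm
        self.config = config
        self.input_dim = input_dim
        rng = np.random.default_rng(config.seed + 31)
        self.conv = nn.Conv2d(rng, 1, cfg.conv_channels, cfg.conv_kernel)
        self.bn = nn.BatchNorm(cfg.conv_channels)
        self.pool_k = cfg.pool_k
        pooled_w = input_dim // cfg.pool_k
        flat = cfg.conv_channels * pooled_w
        self.pieces = [nn.Dense(rng, flat, cfg.maxout_units)
                       for _ in range(cfg.maxout_pieces)]
        self.out = nn.Dense(rng, cfg.maxout_units, 2)

    def logits(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        # run the square k x k kernel over an (N, 1, 1, F) map: with odd k and
        # symmetric padding the output stays one row high, i.e. a 1-D conv
        k = self.conv.weight.shape[2]
        xm = x.reshape(n, 1, 1, self.input_dim)
        y = nn.conv2d(xm, self.conv.weight, self.conv.bias, padding=k // 2)
        y = self.bn(y).relu()
        # crop to a pool-divisible width, then max-pool the sequence axis
        w = self.input_dim - self.input_dim % self.pool_k
        y = y[:, :, 0, :w]
        c = y.shape[1]
        y = _seq_max_pool(y.reshape(n, c, w // self.pool_k, self.pool_k),
                          self.pool_k)
        y = y.reshape(n, -1)
        mo = self.pieces[0](y)
        for piece in self.pieces[1:]:
            mo = mo.maximum(piece(y))
        return self.out(mo)

    def fit(self, features: np.ndarray, labels: np.ndarray) -> dict:
        cfg = self.config.dm
        features = np.asarray(features, dtype=float)
        opt = nn.Adam(self.parameters(), lr=cfg.learning_rate)
        rng = np.random.default_rng(self.config.seed + 41)
        n = len(features)
        history = {"loss": []}
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                opt.zero_grad()
                loss = nn.cross_entropy(self.logits(Tensor(features[idx])),
                                        labels[idx])
                loss.backward()
                opt.step()
                epoch_loss += loss.item() * len(idx)
            history["loss"].append(epoch_loss / n)
        return history

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        self.eval()
        probs = nn.softmax(self.logits(Tensor(np.asarray(features, dtype=float)))).data
        self.train()
        return probs


def _seq_max_pool(y: Tensor, k: int) -> Tensor:
    """Max-pool the last axis of an (N, C, W, k)-reshaped tensor."""
    out = y[:, :, :, 0]
    for i in range(1, k):
        out = out.maximum(y[:, :, :, i])
    return out


def build_deep_maxout(config: ClassifierConfig | None = None,
                      input_dim: int = 201) -> DeepMaxout:
    return DeepMaxout(config or ClassifierConfig(), input_dim)


# -- ensemble ---------------------------------------------------------------

def train_ensemble(images: np.ndarray, feature_vectors: np.ndarray,
                   labels: np.ndarray, config: ClassifierConfig | None = None):
    """Train ILN-TL on segmented images and DeepMaxout on feature vectors.

    Returns ``(iln, dm, histories)``; deterministic for a fixed seed.
    """
    config = config or ClassifierConfig()
    labels = np.asarray(labels, dtype=int)
    if len(images) != len(feature_vectors) or len(images) != len(labels):
        raise ValueError("images, feature_vectors and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    iln = build_iln_tl(config, input_size=np.asarray(images).shape[-1])
    dm = build_deep_maxout(config, input_dim=np.asarray(feature_vectors).shape[-1])
    hist_iln = iln.fit(np.asarray(images, dtype=float), labels)
    hist_dm = dm.fit(feature_vectors, labels)
    return iln, dm, {"iln": hist_iln, "dm": hist_dm}


def soft_vote(prob_rows: np.ndarray,
              weights: np.ndarray | None = None) -> tuple[int, np.ndarray]:
    """Weighted soft vote over classifier probability rows.

    ``prob_rows`` is (c, n_classes); default weights are uniform 0.5 for the
    two-classifier ensemble.  Returns (label, fused probabilities); exact
    ties resolve to class 0 (non-cancer).
    """
    prob_rows = np.atleast_2d(np.asarray(prob_rows, dtype=float))
    if weights is None:
        weights = np.full(prob_rows.shape[0], 1.0 / prob_rows.shape[0])
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != prob_rows.shape[0]:
        raise ValueError("weight count does not match classifier count")
    fused = weights @ prob_rows
    label = int(np.argmax(fused))      # argmax takes the first (lowest) index on ties
    return label, fused
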