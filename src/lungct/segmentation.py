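"""Attention residual U-Net (P-ResU-Net) for lung/nodule segmentation.

The network is an encoder-decoder of pre-activated residual blocks, each
followed by a residual dual-channel attention block (RDCAB).  The RDCAB runs
three parallel branches over a feature stack: global max pooling and global
average pooling each followed by a channel projection and PReLU, whose sum
gated through the improved d-SiLU forms per-channel attention weights; and a
spatial branch (3x3 conv, PReLU, conv).  The attention-weighted input and
the spatial branch are added, passed through the improved d-SiLU again, and
a residual connection adds the block input so attention can never erase
features.  The decoder upsamples, concatenates the matching encoder
attention output, and refines with residual blocks; a final 1x1 convolution
with a sigmoid yields the mask probability map.

Activations
-----------
``prelu``       rectifier with learnable negative slope alpha.
``d_silu``      sigmoid-derivative-weighted linear unit
                F(x) = SF(x) * (1 + x * (1 - SF(x))); the improved variant
                uses SF(x) = logistic(tanh(x)), a bounded dynamic scaling of
                the argument, the conventional variant the plain logistic.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ActivationParams", "SegModelConfig",
    "prelu", "d_silu", "rdcab_forward", "RDCAB", "PResUNet",
    "build_p_resunet", "train_segmenter", "segment", "seg_metrics",
]


@dataclasses.dataclass
class ActivationParams:
    prelu_alpha: float = 0.25
    variant: str = "improved_dsilu"


@dataclasses.dataclass
class SegModelConfig:
    depth: int = 3
    base_channels: int = 8
    input_size: int = 64
    attention_enabled: bool = True
    threshold: float = 0.5
    loss: str = "dice_bce"
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.input_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}")


# -- activations on plain arrays ------------------------------------------

def prelu(x, alpha):
    """x if x > 0 else alpha * x, elementwise."""
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, alpha * x)


def d_silu(x, variant: str = "improved_dsilu"):
    """Sigmoid-derivative-weighted linear unit, improved or conventional."""
    x = np.asarray(x, dtype=float)
    if variant == "improved_dsilu":
        sf = 1.0 / (1.0 + np.exp(-np.tanh(x)))
    elif variant == "conventional_dsilu":
        sf = 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))
    else:
        raise ValueError(f"unknown d-SiLU variant: {variant!r}")
    return sf * (1.0 + x * (1.0 - sf))


# -- building blocks -------------------------------------------------------

class ResidualBlock(nn.Module):
    """Pre-activated residual block: [PReLU -> conv3]x2 plus a skip path."""

    def __init__(self, rng, in_channels: int, out_channels: int):
        super().__init__()
        self.act1 = nn.PReLU(in_channels)
        self.conv1 = nn.Conv2d(rng, in_channels, out_channels, 3)
        self.act2 = nn.PReLU(out_channels)
        self.conv2 = nn.Conv2d(rng, out_channels, out_channels, 3)
        self.skip = (nn.Conv2d(rng, in_channels, out_channels, 1)
                     if in_channels != out_channels else None)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(self.act2(self.conv1(self.act1(x))))
        s = self.skip(x) if self.skip is not None else x
        return y + s


class RDCAB(nn.Module):
    """Residual dual-channel attention block (three parallel branches)."""

    def __init__(self, rng, channels: int, variant: str = "improved_dsilu"):
        super().__init__()
        self.variant = variant
        self.gmp_conv = nn.Conv2d(rng, channels, channels, 1, padding=0)
        self.gmp_act = nn.PReLU(channels)
        self.gap_conv = nn.Conv2d(rng, channels, channels, 1, padding=0)
        self.gap_act = nn.PReLU(channels)
        self.sp_conv1 = nn.Conv2d(rng, channels, channels, 3)
        self.sp_act = nn.PReLU(channels)
        self.sp_conv2 = nn.Conv2d(rng, channels, channels, 3)

    def forward(self, x: Tensor) -> Tensor:
        a = self.gmp_act(self.gmp_conv(nn.global_max_pool(x)))
        b = self.gap_act(self.gap_conv(nn.global_avg_pool(x)))
        attention = nn.tensor_d_silu(a + b, self.variant)      # (N, C, 1, 1)
        spatial = self.sp_conv2(self.sp_act(self.sp_conv1(x)))
        fused = x * attention + spatial
        return nn.tensor_d_silu(fused, self.variant) + x


def rdcab_forward(features: np.ndarray, block: RDCAB) -> np.ndarray:
    """Run an RDCAB on a plain (C, H, W) or (N, C, H, W) feature stack."""
    arr = np.asarray(features, dtype=float)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    out = block.eval()(Tensor(arr)).data
    return out[0] if squeeze else out


# -- network ----------------------------------------------------------------

class PResUNet(nn.Module):
    def __init__(self, config: SegModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        depth, base = config.depth, config.base_channels
        channels = [base * 2 ** d for d in range(depth)]

        self.enc_blocks: list[nn.Module] = []
        self.enc_attn: list[nn.Module] = []
        c_in = 1
        for c in channels:
            self.enc_blocks.append(ResidualBlock(rng, c_in, c))
            self.enc_attn.append(RDCAB(rng, c) if config.attention_enabled
                                 else nn.Sequential())
            c_in = c

        self.dec_blocks: list[nn.Module] = []
        self.dec_attn: list[nn.Module] = []
        for d in range(depth - 2, -1, -1):
            c = channels[d]
            self.dec_blocks.append(ResidualBlock(rng, channels[d + 1] + c, c))
            self.dec_attn.append(RDCAB(rng, c) if config.attention_enabled
                                 else nn.Sequential())
        self.head = nn.Conv2d(rng, channels[0], 1, 1, padding=0)
        # temper the output layer so initial logits stay near zero
        self.head.weight.data *= 0.1

    def forward_logits(self, x: Tensor) -> Tensor:
        skips = []
        depth = self.config.depth
        for d in range(depth):
            x = self.enc_attn[d](self.enc_blocks[d](x))
            if d < depth - 1:
                skips.append(x)
                x = nn.max_pool2d(x, 2)
        for i, d in enumerate(range(depth - 2, -1, -1)):
            x = nn.upsample2x(x)
            x = nn.concat([x, skips[d]], axis=1)
            x = self.dec_attn[i](self.dec_blocks[i](x))
        return self.head(x)

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_logits(x).sigmoid()


def build_p_resunet(config: SegModelConfig) -> PResUNet:
    """Construct a seeded P-ResU-Net; parameter layout is deterministic."""
    return PResUNet(config)


# -- training / inference ---------------------------------------------------

def _dice_bce_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    # BCE in softplus form on the logits: numerically safe and its gradient
    # (p - t) never underflows even when the sigmoid saturates
    t = Tensor(target)
    zabs = logits.relu() + (-logits).relu()
    bce = (logits.relu() - logits * t + (1.0 + (-zabs).exp()).log()).mean()
    pred = logits.sigmoid()
    inter = (pred * t).sum()
    dice = (2.0 * inter + 1.0) / (pred.sum() + t.sum() + 1.0)
    return bce + (1.0 - dice)


def train_segmenter(dataset, config: SegModelConfig):
    """Train a P-ResU-Net on phantom (image, mask) pairs.

    Returns ``(model, loss_history)`` with one mean loss per epoch.
    Deterministic for a fixed ``config.seed``.
    """
    masks = dataset.masks
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if not masks.any():
        raise ValueError("dataset contains no positive mask")
    images = dataset.images[:, None, :, :]           # (N, 1, H, W)
    targets = masks[:, None, :, :].astype(float)
    model = build_p_resunet(config)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(images)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            logits = model.forward_logits(Tensor(images[idx]))
            loss = _dice_bce_loss(logits, targets[idx])
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
        history.append(epoch_loss / n)
    return model, history


def segment(image: np.ndarray, model: PResUNet,
            threshold: float | None = None) -> np.ndarray:
    """Binary mask from thresholding the sigmoid probability map."""
    if threshold is None:
        threshold = model.config.threshold
    image = np.asarray(image, dtype=float)
    if image.shape != (model.config.input_size, model.config.input_size):
        raise ValueError(
            f"image shape {image.shape} does not match model input size "
            f"{model.config.input_size}")
    prob = model.eval()(Tensor(image[None, None])).data[0, 0]
    model.train()
    return (prob > threshold).astype(np.uint8)


def seg_metrics(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Dice, Jaccard and pixel accuracy; empty-vs-empty counts as perfect."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    inter = np.logical_and(pred, truth).sum()
    union = np.logical_or(pred, truth).sum()
    a, b = pred.sum(), truth.sum()
    dice = 1.0 if (a + b) == 0 else 2.0 * inter / (a + b)
    jaccard = 1.0 if union == 0 else inter / union
    accuracy = float(np.mean(pred == truth))
    return {"dice": float(dice), "jaccard": float(jaccard),
            "segmentation_accuracy": accuracy}
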