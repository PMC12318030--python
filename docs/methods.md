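# Methods

This note records the models implemented in `lungct`, the parameter choices
that matter, and what the synthetic benchmark does and does not demonstrate.

## Synthetic phantoms

Each phantom is a square float image in [0, 1]: background intensity 0.65,
two offset ellipses of intensity 0.18 forming a lung field (semi-axes 0.32
and 0.40 of the image side), and zero or more nodules — Gaussian-profile
blobs with a flat bright core (intensity 0.85) of radius r drawn uniformly
from 3–6 px, centred inside the lung field eroded by r so the whole nodule
fits.  The ground-truth mask is the set of core pixels; the label is 1 iff
the mask is non-empty.  Additive Gaussian noise (σ = 0.03 by default, the
speckle model is also available) is clipped back to [0, 1].  Default sizes
are 64×64 for tests and demos; 128×128 works unchanged.

What the phantoms emulate: a class-balanced or Luna16-like imbalanced
(1224:1112) collection of 2-D slices with bright, roughly round lesions on
a dark parenchyma, plus pixel-accurate masks.  What they do not emulate:
Hounsfield-unit physics, vasculature and airway clutter, juxtapleural
nodules, 3-D context, scanner artefacts.  Nodule/background contrast is
high, so classification on phantoms is an easy problem; passing the
benchmark shows the pipeline is wired correctly and can learn, not that it
would reach comparable numbers on clinical CT.

## Preprocessing

The Gaussian kernel is the discrete `exp(-(x²+y²)/(2σ²))` on a
(2r+1)×(2r+1) support, renormalised to unit sum (the continuous prefactor
is irrelevant after renormalisation and mean intensity is preserved).
Border handling is edge-repeating reflection, which avoids dark halos at
the image boundary.  The adaptive rule smooths most where the image is
flat: per-pixel σ(p) = σ_max − (σ_max − σ_min)·v̂(p), where v̂ is the local
intensity variance in a 5×5 window, min–max scaled over the image.  It is
realised by linearly blending a bank of five fixed-σ responses, which keeps
the operation a convex combination of linear filters (and hence exactly
intensity-shift equivariant before clipping).  Defaults: σ ∈ [0.5, 1.5],
radius 3.

PSNR uses MAX = 1.0 on the float contract (255 only when comparing 8-bit
files).  SSIM uses a 7×7 Gaussian-weighted window (σ = window/4), K1 = 0.01,
K2 = 0.03, dynamic range 1.0 — the standard constants.

## Segmentation: P-ResU-Net

Encoder–decoder with pre-activated residual blocks ([PReLU → 3×3 conv] ×2
plus a 1×1 skip where channels change), each followed by a residual
dual-channel attention block (RDCAB).  RDCAB branches: global max pool and
global average pool, each through a 1×1 channel projection and PReLU; their
sum is gated by the improved d-SiLU to give per-channel attention weights;
a parallel spatial branch is 3×3 conv → PReLU → 3×3 conv.  Fusion is
`x·attention + spatial`, passed through the improved d-SiLU again, plus a
residual connection from the block input so attention can never erase
features ("combined" is read as addition; the exact wiring of the branch
diagram is not fully determined, and this reading is shape-safe and keeps
the dual-channel interpretation).

Activations: PReLU with per-channel learnable slope initialised at 0.25;
the improved d-SiLU `F(x) = SF(x)(1 + x(1 − SF(x)))` with
`SF(x) = logistic(tanh(x))`.  Because the gate saturates at logistic(±1)
rather than 0/1, F is asymptotically linear on both sides (slopes
σ(1)(1−σ(1)) and σ(−1)(1−σ(−1))) — an unusual but deliberate property of
the improved variant, implemented exactly as defined.  The conventional
variant (plain logistic gate) is available for comparison.

Desk-scale default: depth 3, base 8 channels (8/16/32), 64×64 input; a
deeper Luna16-scale configuration (depth 5, 512×512) is expressible but not
exercised by tests.  Training: Dice + binary cross-entropy (standard for
class-imbalanced masks; the BCE term is computed in softplus form from the
logits so its gradient never underflows when the sigmoid saturates), Adam
at 1e−3, batch 8, 10 epochs by default, mask threshold 0.5.  The output
1×1 convolution is initialised at one tenth of the He scale so initial
logits stay near zero.  All computation is float64 numpy; training is
bit-reproducible for a fixed seed.

## Features (201 = 50 + 50 + 100 + 1)

**LGTrP (50).**  Gabor filtering with 4 orientations (0°, 45°, 90°, 135°),
wavelength 4 px, envelope σ 2 px; kernels are DC-subtracted, so the
response — the pixelwise maximum complex magnitude over orientations — is
invariant to constant intensity offsets.  On the response map, a two-radius
transition code is computed per pixel: bit l is set iff the intensity rises
strictly outward in direction l at both radii r1 = 1 and r2 = 2
(step(d) = 1 iff d > 0, ties to 0; off-grid samples bilinear; border margin
⌈r2⌉ excluded).  Histograms with 10 equal-width bins over [0, 256) are
taken on the whole map and a 2×2 grid (5 regions), each L1-normalised:
5 × 10 = 50 values.  The layout is the smallest natural one matching the
published total of 50.

**PHOG (50).**  Sobel gradients; orientation is the full-quadrant
arctangent of (G_y, G_x) folded to [0°, 180°) (the printed ratio form of
the orientation equation is resolved to the standard atan2 convention);
magnitude-weighted 10-bin histograms at pyramid levels 0 and 1 (1 + 4
cells), concatenated and L1-normalised once: 10 + 40 = 50.

**Deep features (100).**  Two seed-initialised, forward-only convolutional
encoders — an AlexNet-style plain stack tapped at a 4096-wide dense layer
and a ResNet-style residual stack tapped at a 2048-wide pooled layer —
yield 6144 raw activations per image (3-channel replicated, resized to 64;
224 is configurable but unnecessary at phantom scale).  A single joint PCA
(deterministic full SVD), fitted on the training split only, projects to
100 components.  Fixed random convolutional projections are a standard
feature-extraction technique; they preserve the tap widths and the PCA
reduction of the transfer-learning design while keeping the package fully
offline and seed-deterministic.

**Improved entropy (1).**  Shannon entropy En over 256 levels (intensities
scaled to [0, 255] and floored; 0·log 0 := 0), normalized first-order
entropy NEn = En₁/log₂(N_m) over the N_m distinct values present (0 for a
constant image), and the blend IEn = W·En + (1 − W)·NEn with
W = 2(1 − 1/(1 + e^En)).  Note W ∈ [1, 2), so for En > 0 the NEn term
enters negatively; the formula is applied exactly as defined and this sign
behaviour is intentional.

## Classification

**ILN-TL.**  A frozen VGG-style trunk (two 3×3 conv pairs with relu and
2×2 max-pooling; compact by design so no pretrained weights are needed)
feeds a Gaussian-normalisation layer: per feature,
N_Z = (((X − μ_L)/(3σ)) + 1)/2 with the Lehmer mean μ_L = Σx²/Σx (Q = 2)
and σ the per-feature standard deviation, both frozen from the training
split; outputs are clipped to [0, 1].  If |Σx^(Q−1)| < 1e−8 the arithmetic
mean is used with a warning.  The head is depthwise separable convolution
(5×5) → max pool → min pool → dense(128, relu) → dropout →
dense(128, relu) → dropout → 2-way softmax, trained with categorical
cross-entropy, Adam 1e−3, batch 64, validation split 0.2, 50 epochs.
Because the trunk is frozen its activations are precomputed once, so head
training is cheap; a fine-tune flag unfreezes the trunk.

**DeepMaxout.**  The 201-vector is treated as a 1-D sequence: 16-channel
convolution (kernel 3, realised as a one-row 2-D conv), batch
normalisation, relu, k = 2 max pooling (the odd-width map is cropped to 200
first), then a maxout dense block (3 affine pieces, 64 units) and a 2-way
softmax; Adam 0.01, batch 32, 50 epochs.

**Routing and fusion.**  ILN-TL consumes the segmented image; DeepMaxout
consumes the hand-crafted-plus-deep feature vector; soft voting averages
the two probability rows with weights (0.5, 0.5) and takes the argmax,
with exact ties resolving to non-cancer — the conservative default.

## Evaluation

Train/test splits use the floor rule n_train = ⌊f·n⌋ (the unique rule
consistent with 1401/1635/1868 from 2336 at 60/70/80 %), stratified by
label via largest-remainder allocation so the total is exact.  The report
contains the confusion matrix, accuracy, sensitivity, specificity,
precision, F-measure, MCC, NPV, FPR, FNR (zero denominators report 0 with a
warning so degenerate ablations still produce reports), trapezoidal
ROC-AUC, and mean/median/std/min/max accuracy over seed-varied repeats.
Ablation switches disable preprocessing or segmentation, swap the improved
entropy for plain Shannon entropy, and restrict feature families.

## Problem sizes and numerical choices

The standard benchmark is 200 phantoms at 64×64, split 80/20: segmenter
10 epochs, classifier heads 50 epochs, joint PCA on the 160 training
images.  The capacity check overfits one phantom for 200 epochs.  These
sizes make a full end-to-end run a matter of minutes on a single CPU while
leaving large margins on the benchmark thresholds.  All randomness flows
from one integer seed per run; sub-seeds are derived deterministically.
Ties in max-pooling route gradients to the first occurrence; elementwise
`maximum` routes ties to its first argument.

## Known limitations

- Phantom separability means benchmark accuracy saturates near 1.0; the
  benchmark guards wiring and learning ability, not clinical performance.
- The deep-feature encoders and the ILN-TL trunk are random (untrained)
  projections, not ImageNet-pretrained networks; absolute feature quality
  on real CT would differ.
- The numpy engine is single-threaded-friendly but not fast; Luna16-scale
  training (512×512, thousands of slices) is out of its intended range.
- DICOM/MetaImage readers extract single 2-D slices only.
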