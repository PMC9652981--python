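# Methods

`anisoseg` implements a volumetric segmentation method for gross target
volumes (GTV) on thick-slice radiotherapy planning CT, where the slice
thickness (~5 mm) is about five times the in-plane pixel spacing.  The
model is a five-stage encoder–decoder ("TransResSEUnet2.5D"-style) that
combines three ideas:

1. **2.5D convolution.**  Stages 1–2 (and the matching decoder stages)
   convolve only in-plane: every kernel and stride has extent 1 along the
   slice axis.  Shallow layers therefore learn 2D edge detail, which
   survives the coarse slice sampling, while stages 3–5 convolve in 3D to
   integrate inter-slice semantics.
2. **Residual squeeze-and-excitation units.**  Each stage is built from
   Res-SE blocks: conv → BN → LeakyReLU(0.01) → conv → BN → SE gate →
   (+skip) → LeakyReLU.  Block-A carries the stride/channel change (with a
   strided 1×1×1 projection skip); Block-B is shape-preserving with an
   identity skip.  The SE gate global-average-pools each channel, passes
   the vector through a bottleneck perceptron of width C/r (r = 4, matching
   a minimum channel width of 16 = 64/4 relative to the original SE
   design), and sigmoid-scales each channel.
3. **A residual dual-attention bottleneck.**  Stage 5 downsamples with a
   3D Block-A to C2 channels, linearly maps to C3 channels with a 1×1×1
   convolution, flattens the D2×H2×W2 grid into P tokens (depth-major
   raster order), adds a learnable position embedding (z0 = f + PE) and
   applies M pre-norm Transformer layers
   z\*\_m = MSA(LN(z\_{m−1})) + z\_{m−1},  z\_m = MLP(LN(z\*\_m)) + z\*\_m,
   with H heads (scaled dot-product attention, scale 1/√(C3/H)) and a
   one-hidden-layer perceptron of width h.  Tokens are unflattened in the
   same raster order, mapped back to C2 channels and added to the
   bottleneck input (a residual around the whole transformer).

The decoder mirrors the encoder with transpose-convolution upsampling
(kernel = stride, so even dimensions are restored exactly), skip
concatenation, a 1×1×1 fusion convolution and one shape-preserving block
per stage.  The head is a 1×1×1 convolution to two channels plus a channel
softmax; masks are obtained by thresholding the target channel at 0.5
(ties go to background).

Default full-size plan (patch 32×256×256): channels (16,32,64,128,256),
strides ((1,1,1),(1,2,2),(2,2,2),(2,2,2),(2,2,2)), bottleneck grid 4×16×16
→ P = 1024 tokens, C2 = 256, C3 = 512, M = 4, H = 8, h = 4096.  Six
variants share the factory: `unet2d`, `unet25d`, `unet3d` (plain two-conv
units, no SE/transformer), `resseunet3d`, `resseunet25d`, and
`transresseunet25d`.  The `unet2d`/`unet25d` layouts are reconstructions
(the comparison tables that motivated them give no construction details):
all-2D and 2D-through-stage-2 respectively, plain conv units.  In `unet2d`
depth is never strided, since a 2D stage may not mix slices.

## Numerical engine

No deep-learning framework is used: the package ships a small
reverse-mode autodiff engine over NumPy (`anisoseg.nd`) with exactly the
operations the networks need — convolution as a sum of per-kernel-tap
GEMMs on shifted views, no-overlap transposed convolution (kernel =
stride) as a tensordot + block reshape, batch/layer norm, multi-head
attention built from matmul/softmax primitives, and Adam with classical
coupled L2 weight decay (a decoupled switch exists for comparison).  All
gradients are verified against central finite differences in the test
suite.  Arithmetic is float32; batch-norm statistics accumulate in
float64.  Initialization is He-style with LeakyReLU gain for convolutions
and linear layers, γ=1/β=0 for the norms, N(0, 0.02) for the position
embedding, with a single integer seed determining every weight.

## Training protocol

Adam (lr0 = 1e-3, weight decay 1e-4), polynomial decay
lr = lr0·(1 − epoch/epochs)^0.9 applied per epoch, batch 4, loss = average
soft Dice over the two classes (ε = 1e-5) + mean voxelwise cross-entropy.
Training samples are random crops of the configured patch with
augmentation: per-axis mirror (p = 0.5), in-plane rotation ≤ ±15°,
in-plane scale 0.9–1.1, translation ≤ ±10 % per axis, Gaussian intensity
noise (sd 0.02 in normalized units).  Magnitudes are package defaults
(declared, not derived) and all are config-overridable.  Rotation and
scaling are in-plane only: with 5 mm slices, through-plane resampling
destroys the very anisotropy the architecture exploits.  Validation uses
deterministic crops centered on the reference-mask centroid (rounded
toward zero, clamped at borders) with no augmentation; validation DSC is
computed on hardened (argmax) predictions.  A checkpoint is written only
on strict validation-DSC improvement, so the persisted model is always
the arg-max epoch of the validation trace.  Non-finite losses abort with
the offending epoch/batch.  One random crop per case per epoch is the
default (the source protocol does not state this number).

Full-volume inference tiles the volume with 50 %-overlap sliding windows,
averages softmax probabilities across windows and thresholds at 0.5;
undersized volumes are symmetrically zero-padded and unpadded afterwards.

## Preprocessing

HU volumes are windowed with the soft-tissue window (width 400, level
40): out = clip((hu − (level − width/2))/width, 0, 1)·255, then rescaled
to [0, 1] for the network (the 0–255 → 0–1 rescale is this package's
convention; the source pipeline does not state one).  Padding uses value
0 in the normalized domain, i.e. air after windowing.

## Evaluation metrics

DSC = 2|A∩B|/(|A|+|B|) per patient over the whole volume.  (The source
formula prints "|V_A = V_B|" in the numerator; intersection is the only
reading that keeps the coefficient in [0,1] with that normalizer.)  Both
masks empty is an error (0/0); exactly one empty scores 0.

HD95 = ½[P95 of d(z→S_A) over z∈S_B + P95 of d(z→S_B) over z∈S_A], in mm.
Surfaces are foreground voxels with a 6-neighborhood background voxel
(out-of-bounds counts as background); distances are voxel-center to
voxel-center Euclidean distances under the anisotropic spacing, computed
with an exact Euclidean distance transform; the 95th percentile uses
linear interpolation between order statistics (conventions differ, so
this is pinned).  No sub-voxel surface meshing is attempted.  Empty masks
are an error.  The implementation is verified against an O(n²) pairwise
brute force on random mask pairs.

## Synthetic phantom bench

The generator emulates the thick-slice regime: default 32×96×96 voxels at
(5,1,1) mm — the 512×512 in-plane matrix of clinical planning CT scaled
down to stay CPU-fast while preserving the 5:1 anisotropy — one
soft-tissue lesion (~40 HU, jittered 20–60 HU across a dataset) in
lung-like background (−800 HU) with additive Gaussian noise (sd 20 HU).
Lesion masks are decided analytically at voxel centers ((i + 0.5)·spacing)
in physical mm, with no partial-volume antialiasing, so masks are exactly
checkable against the generating inequality.  "Lobulated" lesions are
unions of n_lobes jittered overlapping ellipsoids (centers jittered up to
0.5 semiaxis, lobe size 0.6 semiaxis, so the union reaches ≤1.1 semiaxes —
the bound used for placement validation).  One master seed spawns named
geometry and noise streams, so changing the noise level never moves a
lesion, and per-case sub-seeds are derived independently of the dataset
size, so any case can be regenerated alone.

What the phantoms do **not** model: lung anatomy, airways, vessels,
respiratory motion, scanner reconstruction kernels, or inter-observer
contour variability.  Passing the phantom bench therefore demonstrates
that the architecture, losses, schedule and metrics are implemented
correctly and that the network can learn a localized lesion under the
stated anisotropy — not that clinical-grade accuracy transfers to real
cohorts, which requires the original training data and GPU-scale runs.

## Scaled-down profiles and problem sizes

The shipped `configs/toy.yaml` profile (patch 16×64×64, channels
(8,16,32,64,128), C3 = 128, h = 256, M = 2, H = 4, 20 phantoms, ≤30
epochs) is the package's CPU bench.  On it, the dual-attention 2.5D
variant typically crosses mean validation DSC 0.85 between epochs 7 and
15 (convergence speed varies with the initialization seed) and settles
near 0.93–0.98 by epoch 30.  The seeded acceptance test trains 12 epochs
at a fixed seed; the reproduction script trains the full 30-epoch bound
so its reported value is robust across seeds.  `configs/paper.yaml`
carries the full-size hyperparameters and is intended for external
clinical data on GPU-class hardware.

## Known limitations

- The transposed convolutions require kernel = stride (exact tiling);
  odd spatial sizes under stride 2 are rejected rather than padded, which
  keeps all shape arithmetic exact.
- The attention MLP activation (unspecified in the source description) is
  LeakyReLU(0.01) for consistency with the rest of the network; "three
  layers with an implicit layer h" is read as input/hidden/output, i.e.
  two weight matrices.
- The position embedding fixes P at build time; inputs with a different
  bottleneck grid are rejected.
- Block-A is "changes channels per config": one part of the source text
  describes it as reducing channels, another as increasing them; the
  factory always uses it to move to the configured stage width.
- Surface distances use voxel centers; metrics on very small structures
  (a few voxels) are therefore quantized by the spacing.
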