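# Methods

`swardseg` estimates the botanical composition of mixed clover/ryegrass
pasture from top-down RGB imagery. This note documents the models and
procedures the package implements, the choices that were genuinely open,
and what the synthetic study conditions do and do not establish.

## Synthetic training data (fixtures + sig)

Dense pasture cannot be labelled pixel-by-pixel at scale, so training
scenes are composed: plant patches are pasted over soil backgrounds with
the label map derived from the patch masks (cut-and-paste synthesis).
Because no plant-sample imagery ships with the package, the `fixtures`
module generates samples procedurally:

- **Clover** — three elliptical leaflets sharing a petiole point, with
  low-amplitude boundary noise. The OBJECT region is a single connected
  component covering 5–80 % of the patch.
- **Grass** — one to three bezier-curved blades 2–6 px wide; every
  connected component has an oriented-bounding-box aspect ratio ≥ 4.
- **Soil** — multi-scale smoothed noise in brown hues, darker on average
  than plant matter.

No morphometry exists for real cropped pasture samples, so leaflet radii,
blade widths and hue ranges are free choices of this package, fixed once.
Hue ranges for the two species (clover 0.26–0.36, grass 0.18–0.28 in HSV)
deliberately overlap and carry per-pixel noise, so colour alone separates
the species well above chance but not perfectly — a network must also use
shape and texture, which is the structure of the real task.

Scene composition follows the painter's algorithm: 2–20 samples per
100×100 scene (2–12 per 64×64 desk scene), each augmented with
horizontal/vertical flips (p = 0.5 each), scale ±25 %, gamma ±10 % and
saturation ±25 %; rotation is off by default because at the working ground
sample distance (~2–3 px/mm) it destroys blade texture. Samples are pasted
without blending; seams act as additional lighting variation. Sample
boundary pixels within 1 px (Chebyshev) of non-object pixels are
relabelled *ignore* so paste artefacts are excluded from the loss.
Clover-vs-grass selection probability is weighted by the grass/clover mean
object-area ratio so expected pixel coverage per species is balanced.

**Drop shadows.** About half of the scenes (a per-image coin) receive
Gaussian drop shadows under every pasted sample: an elliptical Gaussian
alpha mask centred under the sample, σ uniform in 0.5–1.5 × the sample's
equivalent radius, peak darkening uniform in 20–60 %, mild anisotropy
(0.7–1.3). These ranges are declared choices — shadows here vary lighting
for robustness, they do not model a physical illuminant. Shadow parameters
are drawn from a dedicated child stream, so toggling shadows provably
never changes a label map.

**Reproducibility.** All randomness flows from one seed through named
child streams (CRC32-hashed keys), so any sample or scene is reproducible
in isolation. Train and test libraries fold their role into every child
seed and are tagged; building a training dataset from a test-tagged
library raises a contamination error.

**Partial labels.** Real datasets add partially labelled frames for
configurations synthesis cannot produce; each contributes four flip
variants (identity, hflip, vflip, both), so dataset totals satisfy
`total = n_synthetic + 4·n_partial`.

## The network (lcnet)

LC-Net is an encoder–decoder CNN for canopy segmentation. The encoder is
the first five VGG16 blocks (2,2,3,3,3 convolutions of 64–512 channels,
max-pooling after blocks 1–4, deepest stride 16). The primary decoder
branch runs an FC block (three 3×3 convolutions then a 1×1, all at 1024
channels) and three decoder blocks that bilinearly resize the deep
features to the pre-pool outputs of encoder blocks 4, 3 and 2,
concatenate, and mix with two 3×3/128-channel convolutions; it finishes at
stride 2. The secondary branch applies **local context pyramid pooling**
(LCPP) to the deepest encoder features: stride-1 mean pooling at 3×3 and
5×5 (same padding, border windows normalised by their in-bounds pixel
count, so a constant field is a fixed point), concatenation, and two 1×1
conv+ReLU+BN blocks restoring the input channel count. LCPP is an exact
shape-preserving map in space and channels — it supplies context vectors
local to large regions instead of a single global context vector, so the
network stays usable across image sizes and ground sample distances. The
LCPP output is bilinearly resized and 1×1-projected to match the primary
branch, concatenated, mixed twice more, reduced to 3-class logits at
stride 2, bilinearly upsampled ×2 and softmaxed.

Choices that the architecture description leaves open, fixed here:

- Skip connections read the **pre-pool** conv-stack outputs of blocks
  4/3/2; this is the only wiring that yields both a 512-channel 8×8 skip
  for a 64×64 input and stride-2 logits.
- Activation order is convolution → ReLU → batch normalisation
  (deliberate, configurable); the plain-conv encoder has no normalisation.
- The LCPP channel resize is a learned 1×1 projection; the spatial resize
  is bilinear with half-pixel centres (an exact identity at equal sizes).
- `lcpp_enabled=False` gives the ablated variant used in comparisons.

**Substrate.** The network, its gradients, Xavier initialisation and the
Adam optimiser are implemented directly in NumPy (`swardseg.nn`):
stride-1 same-padding im2col convolutions, 2×2 max pooling, batch
normalisation (momentum 0.9, ε = 1e-5), bilinear resize with scatter-add
adjoint. All tensors are NHWC float32; every layer's backward pass is
verified against central finite differences at double precision in the
test suite. Backbone weights are randomly initialised by default; a
pretrained-backbone flag exists but nothing is downloaded.

## Training (training)

The loss is **partial categorical cross-entropy**: the mean of
−log p(true class) over non-ignore pixels. Ignore-pixel logits are never
read, so the loss and its gradients are bit-invariant to them. A batch
with no labelled pixels raises; the loop skips such batches with a log
message. Full-scale defaults follow the published protocol (Adam, lr 5e-5,
batch 24, 400 epochs); desk-scale runs use lr 1e-3 and small batches.

Cut-and-paste scenes have an unusually high share of class-boundary
pixels, and synthetic boundaries carry little information about true leaf
edges; consequently the test **loss** rises after a few epochs while
accuracy and mIoU keep improving. This is documented behaviour, not a
defect — the trainer therefore checkpoints on test mIoU, never on loss,
and no loss-based early stopping is enabled.

## Evaluation (evaluation)

Metrics are confusion-matrix based with ignore pixels excluded from every
tally: per-class accuracy diag/row-sum, per-class IoU
diag/(row+col−diag). "Mean" values are class-weighted; since that phrase
admits two readings, both are computed — frequency weighting (weights =
true-class pixel shares; the default) and the unweighted macro mean —
and every report names its weighting. Zero-support classes are excluded
from aggregates. mIoU ≤ mAcc holds for every matrix and both weightings.
Stratified k-fold cross-validation splits each named sample pool
independently **before** synthetic generation, so no plant sample reaches
two folds' synthetic scenes; fold i aggregates part i of every pool.

## Postprocessing and stitching (postprocess, stitching)

A pixel whose maximum class probability falls below τ = 0.8 is declared
background (confidence = max softmax probability; the package's
definition). Background count is monotone in τ, and τ→0 recovers pure
argmax. The clover/vegetation fraction of a region is
|clover| / (|clover| + |grass|); it is undefined (an error) on regions
with no vegetation. Agreement with harvest dry-matter fractions is
summarised by OLS R².

The stitcher reconstructs a metric top-down mosaic from overlapping
frames: per-pair overlap by exhaustive normalised cross-correlation on
mean-subtracted greyscale bands (peak below 0.4 → pair dropped and
logged); the overlap divided into 22 strips with the central row of each
as representative (even-height bands take row ⌊(h−1)/2⌋ — the lower
median, fixed here since no convention is standard); wheel-encoder travel
linearly interpolated across the overlap for along-track placement, with
per-frame px/mm (supplied as sidecar metadata standing in for live height
sensing) for the across-track axis; and mean accumulation in a 1.2 mm
raster grid. Class maps are stitched with the **same** parameters computed
from the RGB pass, as one-hot vote means finalised by per-cell argmax —
averaging class integers would be meaningless. Argmax ties are broken
toward the lowest class index; tied cells are the one place where
consistent relabelling is not preserved. The pass simulator slides a
virtual camera down a ground-truth texture at 0.14–0.37 m/s and 14 fps
equivalents with exact encoder readings, so round-trip tests isolate
stitching error from odometry error.

## Scales used in tests and the results script

One CPU cannot run 400 epochs at batch 24 on 4,500 images of a 45-million
parameter network, so the learnability checks use a documented desk
scale: 64×64 scenes, backbone width 1/8 (channels 8–64), 64 FC and 32
mixing channels (~0.5 M parameters), Adam 1e-3. The tiny-overfit check
(8 scenes, 200 steps, ≥95 % training pixel accuracy on a majority of 3
seeds) validates the architecture/loss/optimiser stack end to end; the
ablation benchmark (200 train / 50 test scenes, 3 seeds, 6 epochs,
per-epoch evaluation with best-by-mIoU checkpointing) trains full LC-Net
and the no-LCPP variant on a fixed dataset and reports both mean test
mIoUs.

A caveat the benchmark itself demonstrates: on the procedural toy task
the two variants are statistically indistinguishable. Across repeated
seeds the full-minus-ablated mIoU difference is zero within noise
(±0.03–0.06 at 6 epochs; both variants converge to the same value by 10
epochs). The toy scenes are decidable from local colour and shape alone,
so the pyramid-pooled context that separates the variants on real dense
pasture carries no usable signal here; the field-scale ordering between
the variants is not an effect this desk-scale setup can resolve, and the
benchmark should be read as two measurements, not a ranking.
Dataset-composition checks run at the full published scale (100×100,
4,500 + 600 images). Architecture contracts (channel widths 1024/128,
stride-2 logits, LCPP shape preservation, closed-form parameter count)
are checked at the full default configuration.

## What passing tests do and do not show

The fixture generators reproduce the *structural* difficulty of sward
imagery — thin filaments vs compact lobes, occlusion, overlapping colour
distributions, edge-dominated labels — but not its photometric reality:
no specular highlights, no depth-of-field blur, no real soil texture, no
weeds or other species, no motion artefacts. Passing the desk-scale
benchmarks establishes that the pipeline is implemented correctly and that
the architecture can learn such a task; it does not establish field
accuracy, which depends on real imagery and full-scale training. The
published field-scale figures (mean accuracy ≈ 95 %, mIoU ≈ 81 %,
fraction-to-dry-matter R² ≈ 0.8) are not reproducible without the original
camera dataset and GPU-scale training, and the package makes no claim to
them.

## Known limitations

- The NumPy substrate is single-threaded-BLAS fast, not GPU fast; the
  full-scale protocol is available in configuration but impractical here.
- Overlap estimation assumes pure along-track motion (no rotation or
  across-track drift) and a shared frame width.
- `estimate_overlap` scores every feasible overlap; for very tall frames a
  bounded search window from speed/fps priors should be configured via
  `min_overlap_px`/`max_overlap`.
- Partial labels in the CLI `generate` command are emulated by masking a
  band of composed scenes; real partial annotations should be supplied to
  `sig.build_dataset` directly.
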