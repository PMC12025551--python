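# Methods

## Problem and scope

`fractalseg` implements binary semantic segmentation of axial
T2-weighted cervical spinal cord MRI: delineating the cord
cross-sectional area (CSA) and, within it, multiple-sclerosis lesions.
It provides four encoder–decoder architectures — a baseline U-Net and
three fractal variants — together with the standard evaluation suite
(DSC, VOE, RVD, ASD, HD, HD95, recall, precision), the geometric
augmentation/split pipeline, a synthetic phantom generator, and paired
statistical model comparison.

## Architectures

All four models share the U-shaped topology: an encoder of feature
stages separated by 2×2 max pooling, a bottleneck, and a decoder of
nearest-neighbour 2× upsampling (followed by a 2×2 convolution) with
same-resolution skip concatenation, ending in a 1×1 convolution and a
sigmoid pixel output. The conv unit everywhere is 3×3 convolution +
batch normalization + ReLU; batch normalization is applied uniformly in
all four models. Upsampling-then-convolution is used rather than
transposed convolution (the two have identical parameter counts for a
2×2 kernel, which keeps closed-form capacity ledgers comparable with
the textbook U-Net).

The fractal block is the recursive expansion

    f_1(x)     = conv_unit(x)
    f_{C+1}(x) = join( conv_unit(x), f_C(f_C(x)) )

with the join taken as the elementwise mean of the parallel paths (the
FractalNet default; drop-path regularization is not used — dropout
alone regularizes, as in the training regimen below). An order-C block
contains exactly 2^C − 1 conv units and mixes path depths from 1 to
2^(C−1), giving multi-scale receptive fields without extra pooling.

* **unet** — double conv units per stage, identity skips.
* **fractalspinet** — every double-conv group (encoder, bottleneck,
  decoder) replaced by an order-C fractal block; identity skips.
* **att_fractalspinet** — FractalSpiNet plus an additive attention gate
  on each skip: with skip features x and the coarser decoder feature g
  (nearest-upsampled to x's resolution),
  α = σ(ψ(ReLU(W_x·x + W_g·g))) is a one-channel weight map in (0,1)
  and the gated skip is x ⊙ α. W_x, W_g, ψ are 1×1 convolutions;
  the intermediate width is half the skip width.
* **con_fractalunet** — the baseline U-Net whose skip tensors pass
  through an order-C fractal block (width preserved) before
  concatenation; encoder/decoder stay double-conv.

Dropout (rate 0.5) is applied at the two deepest levels (deepest
encoder stage and bottleneck). Weights use variance-scaling (fan-in)
normal initialization with a fixed seed; building a model twice with
the same configuration is bit-identical.

### Capacity calibration

The published description of this model family fixes the totals —
31.4, 109.9, 115.8 and 53.3 million trainable parameters for U-Net,
FractalSpiNet, Att-FractalSpiNet and Con-FractalU-Net — but not the
stage widths or fractal order. We therefore start from the canonical
geometry (input 256×256×1, depth 4, stage widths 64/128/256/512/1024,
fractal order C = 3) and treat the bottleneck width as the free
capacity knob: `calibrate_capacity` runs a deterministic, monotone
integer search for the smallest bottleneck width whose exact count
rounds to the target at one decimal. The calibrated widths (1037,
1096, 1151, 1035) are released as the default configurations and a
regression test re-runs the search. A closed-form per-layer ledger,
written independently of the module introspection, cross-checks
`count_parameters`; with batch normalization off, the canonical U-Net
reproduces the textbook total of 31,030,593 parameters exactly.

## Training engine

No deep-learning framework is used: the models run on a small
reverse-mode automatic-differentiation engine written on NumPy
(`fractalseg.nn`), with convolutions evaluated as BLAS tensor
contractions, float32 throughout. Every operation's gradient is
checked against central-difference numerical differentiation in the
test suite. The training regimen is Adam (β = 0.9/0.999, ε = 1e-7) at
learning rate 0.001, batch size 8, binary cross-entropy computed
stably from logits, sigmoid output, dropout 0.5; the full-scale
schedule is 200 epochs. "Accuracy" in the training curves is pixelwise
binary accuracy at threshold 0.5. The checkpoint with the lowest
validation loss is kept (final-epoch state is also returned); there is
no learning-rate schedule and no early stopping. Masks are produced by
thresholding the sigmoid output at 0.5.

A CPU engine bounds the practical problem size. Tests and the phantom
smoke runs use reduced configurations — 64×64 inputs, depth 3, stage
widths 8/16/32/64, fractal order 2, 30 epochs on 128 slices — chosen
as the package's scaled-down study conditions; each architecture trains
in a few minutes on one core at that size.

## Metrics

For predicted mask PM and ground truth GT (2D, with physical pixel
spacing in mm):

* DSC = 2|PM∩GT| / (|PM|+|GT|) × 100
* VOE = (1 − |PM∩GT|/|PM∪GT|) × 100 (one minus Jaccard)
* RVD = (|PM|−|GT|)/|GT| × 100, signed (over-segmentation positive)
* ASD = (Σ_{s∈S(PM)} d(s,S(GT)) + Σ_{s∈S(GT)} d(s,S(PM))) /
  (|S(PM)|+|S(GT)|), in mm
* HD = max(h(PM,GT), h(GT,PM)) with h the directed maximum of
  point-to-set distances; HD95 replaces each directed maximum by the
  95th percentile (max-of-directed-percentiles, mirroring the max
  structure of plain HD)
* REC = TP/(TP+FN) × 100, PRE = TP/(TP+FP) × 100 (pixelwise)

Boundaries S(·) are foreground pixels with a background 4-neighbour;
image-border pixels count as boundary. Distances are exact Euclidean
distances in mm under per-axis spacing (k-d tree nearest-neighbour
queries; no distance-transform approximation). Percentiles use linear
interpolation between order statistics, making results bit-stable.

Degenerate conventions keep aggregation total and auditable: both masks
empty scores as perfect with a flag; exactly one empty mask scores DSC
0 / VOE 100 and surface distances equal to the image diagonal in mm
(worst case), flag set; RVD and recall are undefined for empty ground
truth (NaN, excluded from means). Two printed-formula ambiguities in
the source description were resolved to the standard definitions: the
DSC denominator is |PM|+|GT| (the typeset union form collapses to the
same quantity plus the intersection), and VOE is 1 − Jaccard (the
typeset denominator reduces to the intersection, which would make the
metric identically zero).

## Phantom generator

The phantom emulates the salient structure of the study data — axial
T2-w slices of 320×250 pixels at 1 mm isotropic spacing in which the
cord occupies a small fraction of the frame: a background tissue level,
a bright CSF annulus (ring thickness 2–4 mm), a darker elliptical cord
(semi-axes 3–5 mm anteroposterior × 4–6.5 mm transverse, jittered
center, small rotation), and Poisson(1.5) hyperintense elliptical
lesions of radius 0.8–2.5 mm placed fully inside the cord with a 1 px
margin (placement is retried up to 25 times; an unplaceable lesion is
dropped and flagged in the pair metadata). Intensity ordering follows
T2-w contrast: background 0.20 < cord 0.45 < CSF 0.85 and cord <
lesion 0.70. A smooth multiplicative bias field (±10%, bilinear
upsampling of a coarse random grid) and additive Gaussian noise
(σ = 0.03) model scanner imperfections; Rician noise is available
behind a flag but Gaussian is the default in this low-noise regime.
Every slice is deterministic in (seed, index).

What the phantom does *not* model: grey-matter "butterfly" morphology,
vertebral and soft-tissue anatomy, partial-volume effects, through-plane
(3D) consistency, or realistic lesion texture. Passing the phantom
trainability tests therefore demonstrates that the architectures,
gradients and training loop work end to end on cord-like geometry — it
does not certify clinical-data performance.

## Augmentation and splitting

Augmentation is purely geometric (pixel-structure preserving):
identity ("same"), in-plane rotation within ±15°, horizontal and
vertical flips, and integer shifts within ±10 px, applied identically
to the image (bilinear) and both masks (nearest-neighbour), which
preserves the lesion-in-cord nesting. The published counts are not an
integer multiple of the source count (231 → 1080), so sources are
cycled round-robin up to the target count with transforms drawn from a
seeded stream. The published ordering — augment first, then split
80/20 (864 training pool / 216 test) — is the default and reproduces
the source-ancestry leakage inherent in that ordering; a
``split_first`` mode provides the leakage-free alternative, and a test
asserts the two modes differ in test-set ancestry. Validation images
(10% of the training pool, which is silent in the source description)
are carved from within the pool, so the 864 figure counts training plus
validation.

## Model comparison

`compare_models` is a two-sided Wilcoxon signed-rank test on paired
per-image scores, zero differences dropped (Wilcoxon's convention),
exact tie-aware null distribution for n ≤ 25 and the normal
approximation with tie correction beyond, no continuity correction.
All-zero differences return p = 1 with a flag. The test suite checks
the implementation against full enumeration of all sign patterns for
n ≤ 8.

## Reproducing results at full scale

The clinical-data headline scores of this model family (mean CSA DSC
near 99% and lesion DSC near 91%) require the original MRI dataset
(publicly deposited at Mendeley Data, `ydkrtmygjp/1`) and GPU-scale
training; they are out of reach of the CPU engine at full resolution
and are deliberately not asserted anywhere in the test suite. The
recipe to attempt them: download the dataset, convert to a manifest
with `fractalseg prep` (preprocessing pads 320×250 to square and
resizes to 256×256), train each architecture with its calibrated
default configuration and the full-scale regimen (`TrainConfig()`
defaults: 200 epochs, batch 8, lr 0.001, dropout 0.5), and evaluate
with `fractalseg eval`. The pipeline code is identical; only the data
and compute differ.

## Numerical and design notes

* Coordinates are (row, col), 0-based, origin top-left; spacing is
  (row_mm, col_mm).
* Even spatial dimensions are required at every pooling stage; inputs
  are padded upstream to multiples of 2^depth.
* Batch-norm running statistics use momentum 0.9 and ε = 1e-5; they are
  part of checkpoints.
* Max-pool ties resolve to the first maximum in block order
  (deterministic).
* The empty-mask surface penalty (image diagonal) is configurable at
  the call site in principle but fixed in `evaluate_pair` for
  comparability across rows.
* Known limitations: no 3D/volumetric metrics, no lesion-instance
  detection metrics, no probability-calibration metrics, single-channel
  input and single-class output only, CPU-bound training speed.
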