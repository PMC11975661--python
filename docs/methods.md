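# Methods

## The measurement problem

The pipeline estimates the dural-sac cross-sectional area (DSCA) of an
axial lumbar slice as the foreground pixel count of a binary segmentation
mask times the physical pixel area, `A = n_fg · s²` with `s` the in-plane
spacing in mm (or `n_fg · s_row · s_col` for anisotropic grids). The
segmentation mask comes from an encoder–decoder network thresholded at
p ≥ 0.5; agreement between predicted and reference areas is summarized by
MAE, Pearson r, and Bland-Altman statistics.

## Phantom model

Real cohorts provide expert masks; this package substitutes a synthetic
phantom whose ground truth is analytic. Each slice contains one
star-convex region with boundary

    r(θ) = r₀ (1 + Σₖ₌₁..K aₖ cos kθ + bₖ sin kθ),

with K = 4 harmonics by default and the total perturbation
Σₖ √(aₖ²+bₖ²) bounded by `perturb_amplitude` (default 0.15, must stay
< 1 so the radius stays positive). The base radius r₀ is scaled so the
1024-vertex boundary polygon's shoelace area equals a target drawn
uniformly from 50–300 mm² — the range spanning severely stenotic through
normal sacs — so `analytic_area_mm2` is exact by construction. The mask
is rasterized by pixel-center inclusion, an unbiased area estimator whose
discrepancy from the polygon area is bounded by perimeter × spacing²
(each boundary-crossing pixel can err by at most its own area, and at
most ~P/s pixels touch the boundary).

Intensities emulate T1 contrast: sac (CSF) dark at 30, an epidural-fat
ring (out to 1.45·r(θ)) bright at 190, background tissue at 110, all in
8-bit units, plus additive Gaussian noise (σ = 6 by default). These
levels are fixed, scanner-realistic contrasts, not tuned quantities.
Per-patient slice counts are drawn from 3–8, and a patient's slices share
a base area modulated ±10% per slice, mimicking adjacent-level
variability. Default geometry is 320×320 pixels at 0.6875 mm spacing;
the benchmark uses 96×96 at the same spacing.

What the phantom does **not** model: vertebral and muscular anatomy,
bias fields, Rician noise statistics, T2 or multi-echo contrast, partial
volume beyond binary rasterization, or 3-D continuity between slices.
Passing the phantom benchmark therefore demonstrates that the
*measurement chain* (preprocessing → segmentation → area → agreement) is
correct and trainable, not that the networks transfer to clinical MRI.

## Preprocessing

Raw 8-bit intensities are divided by 255.0 into [0, 1]. Mask exports are
binarized with foreground = intensity ≥ 150; the ≥ reading (rather than
strict equality at 150) tolerates anti-aliased mask exports whose
foreground sits near 255, and `mode="eq"` preserves the literal rule.
Off-resolution slices are resampled to the 320×320 working grid —
bilinear for images, nearest-neighbor for masks so they stay binary —
with the spacing rescaled by `input_size / target` to preserve physical
extent.

Cross-validation folds are built at patient level: patients are shuffled
with the fold seed and dealt round-robin into k = 5 folds (sizes differ
by ≤ 1). Grouping by patient prevents a subject's 3–8 highly correlated
slices from straddling a train/validation boundary, which would leak.
Within each repetition the held-out fold also serves as the
checkpoint-selection set; this mildly optimistic coupling mirrors a
protocol with a single held-out shard per repetition and is the reason
reported validation accuracies should be read as model-selection values,
not unbiased test estimates.

## Architectures

All three variants map a (H, W) slice in [0, 1] to per-pixel foreground
probabilities through a terminal sigmoid, use "same" padding throughout
(so skip tensors concatenate without cropping), ReLU activations, 2×2
max-pooling, and 2×2 stride-2 transposed-convolution upsampling. Batch
normalization is omitted. Channel counts double per level from
`base_filters` (16 by default; 8 in the desk-scale profile) over `depth`
levels (4 by default; 3 in the benchmark, where 96 = 2³·12 and the extra
level buys little at that field of view).

- **U-Net**: two 3×3 convolutions per level; skip concatenation.
- **Attention U-Net**: each skip tensor x is modulated by
  α = σ(ψ(ReLU(W_g·g + W_x·x))) computed against the upsampled decoder
  signal g, with the gate's internal width half the skip width and ψ a
  single-channel 1×1 convolution; the skip contribution is α ⊙ x.
- **MultiResUNet**: every block chains three 3×3 convolutions whose
  concatenated outputs are summed with a 1×1 shortcut; the channel
  budget W = round(α·U) (α = 1.67) splits as
  ⌊W/6⌋, ⌊W/3⌋, W−⌊W/6⌋−⌊W/3⌋, which sums to W exactly. Skip
  connections are ResPaths of residual 3×3+1×1 units, `depth − level`
  units at encoder level `level`, so the shallowest (most "raw") skip is
  filtered most.

Weights use He-normal initialization for ReLU convolutions and
Xavier-normal for linear/gating ones, fully determined by the configured seed.

### The numerical substrate

The networks run on a small in-package reverse-mode autodiff
(`dsca._autograd`) over float32 numpy arrays in channels-last layout.
Convolutions are computed by shift-and-matmul: one GEMM per kernel offset
against a contiguous copy of the shifted, padded input — the layout that
keeps single-CPU training tractable. Gradients of every primitive
(conv, transposed conv, max-pool with first-quadrant tie-breaking, gate
arithmetic, weighted BCE) are verified against central finite differences
in float64; whole-network directional derivatives agree up to the
nondifferentiability noise contributed by ReLU/max-pool kinks. The
module dtype can be switched to float64 for such verification.

## Training

Loss: mean over pixels and batch of
`−[w₊ y log p + w₋ (1−y) log(1−p)]` with w₊ = 20, w₋ = 1; probabilities
are clamped to [1e−7, 1−1e−7] before the log. Internally the loss is
evaluated from logits via log-add-exp (identical value, no overflow).
The mean reduction keeps the weight semantics independent of image size.
The 20:1 weighting counters the ~1:200 foreground:background imbalance;
its side effect — visible in all results — is near-perfect recall bought
with a systematic one-boundary-ring overestimation of area (positive
Bland-Altman mean difference).

Optimization: Adam at step size 1e−3 (the optimizer's conventional
default; no schedule), batch size 8, 20 epochs by default (8 in the
benchmark). After every epoch the validation loss is computed and the
best parameter state retained; reported accuracies come from that state.
Divergence (non-finite loss) aborts with the epoch index. A single run
seed covers initialization and batch shuffling; there is no augmentation.

## Statistics

Pixel metrics pool one confusion table over all evaluated slices (one
precision/recall/F1 per model); ratios with zero denominators report 0.0
and are logged. MAE is the mean |predicted − true| area. Pearson r is
the sample product-moment coefficient over per-slice area pairs (scipy),
undefined-for-constant-series reported as NaN with a warning.
Bland-Altman differences are predicted − actual (positive mean =
overestimation), the SD uses the n−1 denominator, and the limits are
d̄ ± 1.96 s_d exactly. Every statistic is cross-checked in the test
suite against independent explicit-loop implementations to 1e−10.

## Benchmark problem sizes

The end-to-end benchmark trains each variant on 300 phantom slices and
evaluates on 60 held-out slices (disjoint patients) at 96×96, depth 3,
8 base filters, 8 epochs, batch 8 — sizes chosen so the full
three-architecture run completes in minutes on one CPU while leaving the
task nontrivial (noise, shape variation, patient grouping). Thresholds
asserted there (pooled F1 ≥ 0.80, Pearson ≥ 0.95, MAE ≤ 15 mm²,
MultiResUNet MAE ≤ U-Net MAE + 5 mm²) are recovery criteria on the
phantom's known truth.

## Degenerate inputs and tie-breaks

- Prediction threshold is 0.5 with ≥ semantics; `threshold=0` yields an
  all-foreground mask.
- Max-pool gradients go to the first quadrant attaining the maximum
  (deterministic under ties, which are common after ReLU zeros).
- `calculate_area` rejects non-binary masks and non-positive spacings;
  empty masks give area 0.
- Pearson requires n ≥ 3 and nonzero variance; Bland-Altman n ≥ 2, and
  constant differences collapse the limits onto the mean.
- Phantom configs whose perturbation amplitude reaches 1 (possible
  negative radius), whose sac cannot fit the field of view, or whose
  "sac" is not darker than its surroundings are rejected.

## Known limitations

- Phantom realism as listed above; headline clinical numbers from real
  cohorts are not reproducible from phantoms and are not claimed.
- The held-out fold doubles as the checkpoint selector (optimistic bias).
- Desk-scale networks (≈10⁵ parameters) are far smaller than clinical
  segmentation models; the architecture comparisons here are directional,
  not calibrated effect sizes.
- Single-slice 2-D analysis only; no diameters or 3-D shape descriptors.
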