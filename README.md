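# dsca — automated dural-sac cross-sectional-area quantification

The dural sac is the CSF-filled membrane sac enclosing the cauda equina;
its in-plane cross-sectional area (DSCA, mm²) on axial lumbar MRI is a
standard severity measure for lumbar spinal canal stenosis. Measuring it
by hand is slow and rater-dependent. `dsca` implements an automated
measurement pipeline for researchers who want to train, validate, and
audit such a system end to end:

1. **Phantom generation** — synthetic axial T1-like slices containing a
   single hypointense sac with a radial-Fourier boundary
   `r(θ) = r₀(1 + Σₖ aₖcos kθ + bₖsin kθ)` whose shoelace polygon area is
   known exactly, so every later stage can be scored against an analytic
   ground truth without any patient data.
2. **Preprocessing** — intensities scaled by 255.0 into [0, 1], ground-
   truth mask exports binarized at the 150/255 threshold, off-resolution
   slices resampled to the 320×320 working grid, and patient-grouped
   5-fold cross-validation splits.
3. **Segmentation** — three encoder–decoder networks built on an
   in-package numpy autodiff: a plain U-Net, an Attention U-Net with
   additive attention gates `α = σ(ψ(ReLU(W_g g + W_x x)))` on each skip
   connection, and a MultiResUNet with MultiRes blocks and ResPath skips.
4. **Training** — class-weighted binary cross-entropy
   `−mean(w₊ y log p + w₋ (1−y) log(1−p))` with `w₊:w₋ = 20:1` (the sac
   covers well under 1% of a slice), Adam, batch size 8, and retention of
   the parameter state with the lowest validation loss.
5. **Quantification & agreement** — `area = n_foreground · spacing²`,
   then MAE, Pearson r, and Bland-Altman analysis (mean difference
   `d̄` and limits of agreement `d̄ ± 1.96 s_d`) between predicted and
   true areas, plus pooled pixel precision/recall/F1.

## Worked example

```python
from dsca.pipeline import run_benchmark

outcomes = run_benchmark(seed=1, variants=("unet",))
o = outcomes["unet"]
print(f"pooled F1      {o.metrics.f1:.4f}")
print(f"Pearson r      {o.agreement.pearson_r:.4f}")
print(f"MAE            {o.mae_mm2:.2f} mm^2")
print(f"mean diff      {o.agreement.mean_diff_mm2:.2f} mm^2")
print(f"LoA            [{o.agreement.loa_low:.2f}, {o.agreement.loa_high:.2f}] mm^2")
```

prints (300 training and 60 held-out phantom slices at 96×96, 8 epochs):

```
pooled F1      0.9794
Pearson r      0.9996
MAE            8.69 mm^2
mean diff      8.69 mm^2
LoA            [5.01, 12.37] mm^2
```

The F1 pools pixel-wise true/false positives over all held-out slices;
the Pearson r says predicted and true areas co-vary almost perfectly; the
positive mean difference shows the 20:1 class weighting buys its high
recall with a mild systematic overestimation of the sac boundary, which
the Bland-Altman limits bound at roughly one pixel-ring of area.

The same stages are scriptable from a shell:

```bash
dsca phantom --out cohort --n-patients 50 --seed 7
dsca train --manifest cohort/manifest.csv --variant multires_unet --folds 5 --seed 7 --out run
dsca evaluate --manifest cohort/manifest.csv --checkpoint run/multires_unet_fold0.npz --out report
```

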