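# mexpt2 — adaptive multiexponential T2 relaxometry

Quantitative T2 relaxometry of multi-echo spin-echo (CPMG) MRI for adipocytic
tissue. Water in fat-containing tumours relaxes with more than one time
constant: a short pool (lipid-associated, T2 ≲ 120 ms) and a long pool (free
water). Benign lipomatous tissue decays almost purely biexponentially, while
higher-grade liposarcomas contain growing fractions of voxels that are better
described by a single exponential. `mexpt2` turns that observation into a
per-voxel analysis and a benign/malignant classifier, and ships a synthetic
phantom generator so the whole chain is testable with known ground truth.

## Model

For a voxel sampled at echo times TE_k (k = 1..K) with mean background noise
e(TE_k) estimated from an air region,

    S(TE_k) − e(TE_k) = Σ_{i=1..N} A_i · exp(−TE_k / T2_i),   N ∈ {1, 2}

Both model orders are fitted by bounded trust-region non-linear least squares
(amplitudes in [0, 2000] a.u.; mono T2 ∈ [27, 2500] ms; biexponential
T2₁ ∈ [27, 120] ms, T2₂ ∈ [120.1, 2500] ms). The order kept per voxel is the
one with the higher adjusted R²,

    adj R² = 1 − (1 − R²)(K − 1)/(K − m − 1),   m = 2N,

which penalises the two extra degrees of freedom of the biexponential model;
exact ties resolve to the monoexponential fit by parsimony. The default
acquisition is 25 equidistant echoes (13.4 … 335 ms); the first echo is
excluded (B1-inhomogeneity bias), leaving K = 24 effective echoes from
26.8 ms.

Downstream, ROI results become: mono/bi prevalence percentages and parameter
summaries, amplitude-weighted T2 spectra, a regularized nonnegative
inverse-Laplace T2 distribution of the ROI-mean decay (independent
cross-check of the discrete fits), and stratified 5-fold univariate logistic
regressions on seven per-ROI metrics (mono prevalence; mean/SD/90th
percentile of T2₁ and T2₂) reporting sensitivity and specificity with
malignant as the positive class.

## Worked example

Fit one noisy subcutaneous-fat voxel (two pools: 504 a.u. at 45 ms plus
751 a.u. at 191 ms, gaussian noise σ = 5 a.u.):

```python
import numpy as np
from mexpt2 import (AcquisitionProtocol, simulate_decay,
                    fit_monoexponential, fit_biexponential, select_model)

tes = AcquisitionProtocol.default().effective_tes
rng = np.random.default_rng(0)
y = simulate_decay(504, 45, 751, 191, tes=tes) + rng.normal(0, 5, tes.size)
mono = fit_monoexponential(y, tes)
bi = fit_biexponential(y, tes)
best = select_model(mono, bi)
print(f"mono adj R2 = {mono.adj_r2:.5f}")
print(f"bi   adj R2 = {bi.adj_r2:.5f}")
print(f"selected N = {best.model_order}: A = {np.round(best.A, 1)}, "
      f"T2 = {np.round(best.T2, 1)} ms")
```

prints

```
mono adj R2 = 0.98881
bi   adj R2 = 0.99965
selected N = 2: A = [560.8 668.5], T2 = [ 54.2 205.5] ms
```

The biexponential model wins on adjusted R² and the recovered time constants
bracket the generating values; the scatter of single-voxel estimates (54 vs
45 ms here) is the expected ill-conditioning of two-pool fits at finite SNR,
which is why ROI-level summaries, not single voxels, feed the classifier.

The full synthetic study — phantom, noise estimation, voxelwise fitting, ROI
summaries, inverse-Laplace spectra, classification — runs from the shell:

```sh
mexpt2 run-all --seed 1 --out out/
```

and writes `report.md`, `report.json` and the per-stage CSVs into `out/`.
Individual stages are available as `mexpt2 simulate|fit|summarize|ilt|classify`.

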