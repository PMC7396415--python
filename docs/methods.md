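# Methods

## Signal model and preprocessing

Each voxel of a single-slice multi-echo spin-echo acquisition is modelled as a
sum of up to two exponential decays,

    S(TE_k) − e(TE_k) = Σ_{i=1..N} A_i exp(−TE_k / T2_i),  N ∈ {1, 2},

where e(TE_k) is the mean magnitude of a signal-free background region at
each echo. The default protocol has 25 equidistant echoes (first TE 13.4 ms,
spacing 13.4 ms, TR 2500 ms). The first acquired echo is systematically biased
in alternating-refocusing echo trains and is dropped rather than extrapolated
— extrapolation would require committing to a decay model before model
selection — so fitting uses K = 24 echoes from 26.8 ms. That first effective
echo also sets the floor of detectable T2 (27 ms): shorter, tightly bound
water pools are invisible to this protocol, which is why the model order is
capped at two.

Background subtraction is linear and unclipped: negative post-subtraction
values in the noise-dominated tail are retained, because clipping at zero
would bias the least-squares objective upward in the tail (a `clip_negative`
flag exists for sensitivity analysis). Voxels whose mean corrected signal
over the first three effective echoes falls below 2× the mean background are
flagged ineligible instead of fitted; with the default zero-mean noise model
this floor reduces to "positive early signal".

## Fitting and model selection

Both model orders are fitted per voxel by bounded trust-region least squares
(`scipy.optimize.least_squares`, method `trf`, analytic Jacobians, relative
cost tolerance 1e-10, step tolerance 1e-12, at most 400 function evaluations
per start). Search spaces: amplitudes [0, 2000] a.u.; mono T2 [27, 2500] ms;
bi T2₁ [27, 120] ms and T2₂ [120.1, 2500] ms. The disjoint T2 intervals make
the two-pool model identifiable (components cannot swap) without any penalty
term. Amplitude bounds are independent per component; no joint constraint on
A₁ + A₂ is imposed.

Because the objective is multimodal in the T2s, fitting is multi-start over a
fixed, deterministic grid: 3 log-spaced T2 starts for the mono model, a 3×3
log-spaced (T2₁, T2₂) grid for the bi model, with starting amplitudes set by
linear least squares on the exponential basis of the starting T2s (clipped
into bounds). The best final residual wins; with fixed inputs the whole
voxelwise pass is run-to-run identical. A fit counts as converged if the
optimizer stopped on a tolerance or the residual is numerically zero (the
iteration-cap case on noiseless data).

Model order is chosen by adjusted R²:

    R²     = 1 − Σ(y_i − G_i)² / Σ(y_i − ȳ)²
    adj R² = 1 − (1 − R²)(K − 1)/(K − m − 1)

with m read as the number of free parameters: m = 2 (mono) and m = 4 (bi).
This choice of m shifts the mono/bi tie point and is therefore stated
prominently. Ties within 1e-12 in adjusted R² resolve to the monoexponential
model by parsimony — this is what makes noiseless monoexponential data
(where both models reach R² = 1) resolve to N = 1. If only one model
converged it is kept; if neither, the voxel is marked unfitted (model 0,
NaN in all component maps) and excluded from prevalence denominators.

## Synthetic phantoms

The generator emulates the study conditions on a 2-D grid: rectangular or
disc-shaped tissue regions over a signal-free background, one magnitude image
per acquired echo (all 25, so preprocessing genuinely drops one). Each tissue
class is parametrised by its monoexponential voxel fraction and the
amplitude/T2 of both pools; the bundled presets carry the published per-class
fit statistics for lipoma, well-differentiated, myxoid, poorly
differentiated and pleomorphic liposarcoma, and healthy adipose tissue
(e.g. adipose: 100% biexponential, A₁ = 504, T2₁ = 45 ms, A₂ = 751,
T2₂ = 191 ms). Classes whose published row has (near-)zero mono prevalence
report no mono parameters; their presets fall back to amplitude-weighted
biexponential values so a rare mono draw is still physically plausible.

Per-voxel biological variation is a per-parameter relative SD (defaults
derived from the published SD columns): normal multiplicative jitter on
amplitudes clipped at zero, median-preserving log-normal jitter on T2s, with
rejection to keep T2₁ < T2₂. A voxel's model order is Bernoulli in the class
mono fraction. One `numpy` generator stream seeded by a single integer drives
the whole phantom, so equal (spec, seed) gives bit-identical output.

Noise: the default is signed additive gaussian noise on the magnitude images.
This keeps the background zero-mean and the mean-background subtraction
linear and unbiased, consistent with the preprocessing model above; the
background's per-echo SD then equals the nominal sigma. A `rician` option
(magnitude of a complex gaussian) models real magnitude statistics — its
background is nonnegative with mean σ√(π/2) — but introduces the Rician
floor that linear subtraction only partially removes. No published background
noise level exists for the reference acquisition, so the default
σ = 5 a.u. (SNR ≈ 190 at the first effective echo for adipose-like signal) is
a configuration choice stated here, not an inferred constant.

What the phantom does *not* emulate: k-space/coil effects, B1 fields,
stimulated echoes, partial-volume mixing at region borders, and spatial
correlation of tissue parameters. Passing tests therefore validate the
numerics and logic of the pipeline, not robustness to those acquisition
physics.

## ROI summaries and spectra

Prevalence percentages are computed over fitted voxels only (the metadata
records this denominator). Parameter summaries are mean ± SD per model
population; empty populations are reported absent rather than zero.

T2 spectra are amplitude-weighted: each fitted voxel contributes point masses
at its T2 values, weighted by the matching amplitudes, on a log-spaced grid
(default 27–2500 ms, 200 points) smoothed with a gaussian kernel in log10(T2)
(default width 0.05 log10-ms). Each contribution's kernel is renormalized on
the finite grid, so total spectral mass equals the summed amplitudes exactly,
for any smoothing width including zero (pure histogram). A voxel-count
(unweighted) reading was the alternative; amplitude weighting was chosen
because it reproduces smooth bimodal tissue spectra whose cluster masses are
directly comparable with the inverse-Laplace distribution.

## Inverse Laplace cross-check

The ROI-mean decay (noise-subtracted) is inverted by regularized nonnegative
least squares: minimise ‖Kf − y‖² + λ²‖Lf‖² with f ≥ 0, K_kj =
exp(−TE_k/T2_j) on the same log grid, and L the second-difference (curvature)
operator by default (identity available). The default λ = 0.01 suits
high-SNR ROI means; `choose_lambda` picks the L-curve corner from a log-spaced
sweep when noise levels vary. The inversion runs on ROI-mean signals only —
it is the volume-level reference method against which the voxelwise discrete
fits are compared, not a mapping method. Agreement is asserted structurally
(two mass clusters within one grid spacing of the discrete T2 estimates on
two-pool data), not against any external implementation, since the reference
algorithm's grid and regularization are not published.

## Classification

The unit of analysis is the ROI (one feature row per region/patient). Seven
metrics: mono prevalence (%), and mean/SD/90th percentile (linear
interpolation between order statistics) of the short and long T2 populations.
The short population pools the short component of biexponential voxels with
the single T2 of monoexponential voxels; the long population exists only
where biexponential voxels do — all-mono ROIs are excluded from long-T2
metrics with a warning.

Each metric is evaluated in its own univariate logistic regression (plain
maximum likelihood — `C=inf`, no regularization, documented because library
defaults differ), under stratified k-fold cross-validation (default 5 folds,
seed-deterministic shuffling; folds reduce with a warning when the smaller
class is too small). Sensitivity and specificity come from pooled out-of-fold
predictions at a 0.5 probability threshold, malignant positive, and are
recomputable from the saved per-ROI prediction table.

## Numerical and design notes

- Problem sizes in tests and the acceptance script (hundreds to 1,000 voxels,
  500 recovery replicates, 40-ROI cohorts) were chosen as the smallest sizes
  at which the statistical assertions have comfortable margins.
- Two-pool parameter recovery is information-limited: at σ = 1% of the
  first-echo signal, the Cramér–Rao bound on the short T2 exceeds 19%
  relative SD when the pools are separated only ~4-fold (as in real
  adipocytic tissue), regardless of estimator. The recovery benchmark
  therefore uses a well-separated two-pool phantom (40 vs 600 ms, equal
  amplitudes), where the bound permits <10% median error for every
  parameter; the bias/RMSE of the tissue-like case is reported alongside.
- The goodness-of-fit formulas are validated against an independently coded
  evaluation to 1e-12 at unit scale (magnitude-scaled where |R²| ≫ 1, where
  a fixed absolute tolerance would be below double precision).
- Pipeline outputs carry provenance (seed, config hash, package version) and
  no timestamps, so a fixed seed yields byte-identical report bundles.

## Known limitations

- No three-component fitting, no T2*/T1 modelling, no spatial regularization
  across voxels, no voxelwise inverse-Laplace mapping.
- No first-echo extrapolation and no Rician bias correction by default; with
  `rician` noise the subtracted background mean only approximates the
  signal-dependent Rician floor.
- Single-feature classifiers only; the multi-class tissue-subtype problem is
  out of scope.
- DICOM ingestion and GUI visualisation are out of scope; I/O is NIfTI + CSV
  + JSON.
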