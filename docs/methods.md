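# Methods

This note documents the modeling choices behind `threshmap`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the package's known limitations.

## Data model

A threshold map lives on a rectangular electrode grid with row-major
integer ids; electrode `(r, c)` sits at `(c·pitch, r·pitch)` with
`pitch = 1` by default, so all distances — including the length-scale
bounds below — are expressed in inter-electrode spacings. The physical
pitch of a given device is irrelevant to the model as long as the grid is
regular, which is why no μm geometry is carried.

Thresholds are measured on a 60-step geometric amplitude ladder from 40 to
677 μA (consecutive ratio `(677/40)^(1/59) ≈ 1.049`). The upper end is a
device safety limit: an electrode whose true threshold exceeds it is
recorded *at* 677 μA and flagged **censored**. Censored values are only
lower bounds, so by default they are excluded from GP training and from
held-out scoring (`include_censored` flips both); a censored-likelihood
(Tobit) treatment is out of scope. Inactive (broken/disabled) electrodes
carry no threshold but may still be predicted.

## Gaussian-process model

Targets are transformed before fitting: `z = (log10(y) − m) / s`, with `m`
and `s` the mean and population standard deviation of the training values.
Thresholds span orders of magnitude and the signal-variance box (0.1, 10)
is only meaningful for unit-scale targets, so the log10 + standardize
default makes the bounds interpretable; `use_log=False` disables the log
step. The transform is stored with the fit and inverted exactly for
predictions in μA (which are therefore always positive). A zero-spread
training set clamps `s = 1` with a warning rather than failing.

Kernels (see README for formulas): RBF, Matérn ν = 3/2, and a hybrid
`σ²[α·RBF_unit(ℓ₁) + (1−α)·Matérn_unit(ℓ₂)]` in which both components are
evaluated at unit variance and share one signal variance σ². The mix weight
α is a free parameter in [0, 1], optimized jointly with the length scales
(initial value 0.5). A single isotropic length scale per component is used;
no per-axis anisotropy.

Hyperparameter boxes: σ² ∈ (0.1, 10), every ℓ ∈ (1, 50) pitch units,
σₙ² ∈ (1e−5, 1) with initial 0.1. The noise floor keeps the Cholesky
factorization well conditioned; a further 1e−10 diagonal jitter is added
before every factorization and is considered part of the model covariance.

Fitting maximizes the log marginal likelihood with L-BFGS-B over box
bounds; variances and length scales are optimized in log10 coordinates, α
linearly. The first start uses the defaults (σ² = 1, ℓ = 5, α = 0.5,
σₙ² = 0.1); the remaining `n_restarts − 1` starts (10 restarts by default)
are drawn uniformly in optimizer coordinates from the seeded generator, so
fits are deterministic given (data, config, seed). A restart that ends
worse than its own starting point is discarded in favor of the starting
point, so the achieved LML never falls below the best evaluated initial
value.

Prediction is the standard GP posterior in transformed space,
`μ* = k*ᵀ(K + σₙ²I)⁻¹z`, `v* = k** − k*ᵀ(K + σₙ²I)⁻¹k*`, computed via
Cholesky solves. The reported variance is that of the latent (noise-free)
function: it is bounded by σₙ² at training electrodes and tends to σ² far
from all data. Negative round-off variances are clamped at zero (tolerance
1e−10). Single-electrode training sets are allowed but flagged; the
posterior then mostly reverts to the prior.

## Sampling strategies

*Uniform*: draw without replacement from the eligible (active,
non-censored) set.

*Spatial (Poisson-disk)*: discrete Bridson-style sampling. The initial
radius is `r₀ = √(W·H/n)` for grid extent W × H — the spacing at which n
disks tile the array; candidates are grid electrodes in the annulus
[r, 2r] around a frontier point, accepted if ≥ r from every selected
electrode, with 30 attempts before a frontier point retires. Because the
benchmark needs exactly n electrodes while plain Poisson-disk sampling may
terminate early, a stalled radius first admits any electrode that still
honors the spacing and otherwise shrinks r by 0.8 and resumes. The final
(smallest) radius is recorded in the plan, and the guarantee "all pairwise
distances ≥ final radius" holds for every plan.

*Adaptive*: `n_init = 5` electrodes drawn uniformly, then one electrode
per iteration — the unmeasured one with the largest posterior standard
deviation, ties broken toward the lowest id for determinism.
Hyperparameters are re-optimized every iteration by default;
`GPConfig(optimize=False)` freezes them for speed or for analyzing the
acquisition in isolation.

## Benchmark and statistics

`run_benchmark` sweeps (map × kernel × strategy × n × iteration). The
per-cell seed is derived from the base seed and every factor *except* the
kernel family, so kernel contrasts are paired on identical training sets;
strategy contrasts are matched on (map, n, iteration) with independent
strategy-specific plans. Each iteration re-randomizes both the sampling
plan and the optimizer restarts from the cell seed. MAPE is computed in
linear μA over the held-out set (active, non-censored, unsampled); a cell
with no evaluable held-out electrode is kept as a flagged invalid row.
Summaries report the mean and the SEM (sample sd / √iterations).

`compare_wilcoxon` runs a two-sided Wilcoxon signed-rank test on paired
MAPE differences: zero differences are dropped (the classic convention),
the exact null distribution is used up to 25 non-zero pairs, and the
normal approximation with continuity correction above that. Significance
is read at 0.05 with no multiple-testing correction. If every paired
difference is zero the result is reported as undefined rather than p = 1.

## Synthetic generator

The generator emulates the qualitative structure of clinical threshold
maps on the log10 scale: latent field = baseline + draw from a zero-mean
Gaussian field with squared-exponential covariance (length scale 3.0
pitch units, sd 0.25 log10 units) + rectangular patch offsets; observed
value = latent + independent noise (sd 0.02 log10 ≈ 4.7% relative), then
conversion to μA, snapping to the amplitude ladder, clamping to
[40, 677] μA with censoring flags at the ceiling, and a 5% independent
dead-electrode probability. Defaults were chosen once as plausible for a
6 × 10 epiretinal array whose thresholds mostly sit between ~60 and
~400 μA: the 0.02 noise floor corresponds to a repeat-measurement
variability of a few percent, and a 3-pitch correlation length makes a
well-spread 20-electrode sample informative about the whole array.

Presets: `smooth` (no patches), `patchy` (two random 2×3 patches at ±0.5
log10 — the regime where the Matérn kernel's weaker smoothness commitment
should pay off), and `censored-heavy` (baseline log10(500) so a sizable
fraction of electrodes censors).

What the generator does **not** emulate: trial-by-trial psychophysics and
lapses, threshold drift between sessions, impedance or eccentricity
covariates, and non-stationary correlation structure. The latent field is
deliberately squared-exponential — i.e. the RBF kernel's own assumption —
so benchmark results on smooth presets are a *favorable* regime for RBF;
the patchy preset adds the discontinuities that advantage Matérn. Passing
benchmarks on these maps demonstrates the machinery is correct and the
qualitative kernel ranking reproduces under discontinuities, not that the
same MAPE levels will be attained on any particular patient's data.

## Problem sizes and numerics

The packaged benchmark (`scripts/acceptance.py`) uses 10 smooth-preset
maps × 10 iterations at n ∈ {20, 50} with the Matérn kernel and spatial
sampling — 100 fits per sample size, a few minutes on one CPU. Gradients
of the LML are taken by L-BFGS-B's finite differences; with at most five
hyperparameters and ≤ 60-point covariance matrices, analytic gradients
were not worth the complexity. Ties in the adaptive acquisition and in
ladder snapping are broken deterministically (lowest id; nearest ladder
value in log space).

## Known limitations

- Censored electrodes are simply excluded; a Tobit-style censored
  likelihood would use them properly.
- Only 2-D electrode position enters the model; impedance, eccentricity,
  and patient covariates are natural extensions of the input space.
- The hybrid kernel's α is optimized by LML, which with small training
  sets can sit at either boundary; the fit records the value actually
  reached.
- Poisson-disk sampling on a 60-electrode grid at large n necessarily
  shrinks the radius below one pitch, at which point it behaves close to
  uniform sampling over the remaining electrodes.
- The per-map inactive-electrode sets of real devices are user input; the
  generator's 5% dead rate is a stand-in, not an estimate.
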