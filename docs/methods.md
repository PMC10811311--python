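# Methods

## The reference model

Normal lung weight in growing domestic pigs is not proportional to body
weight: the lung weight index (LWI, g/kg) declines roughly
exponentially over the 16–50 kg range. The package models this as

    LWI(BW) = a · 10^(b · BW)

so that log₁₀(LWI) is linear in BW. The published parameters carried as
`PORCINE_REFERENCE` are a = 26.26 g/kg and b = −0.011 kg⁻¹, with
parameter-wise 95% CI band curves `PORCINE_REFERENCE_UPPER`
(28.84, −0.009) and `PORCINE_REFERENCE_LOWER` (23.44, −0.013).
The model's assumptions: a single smooth allometric trend across
animals pooled from heterogeneous source studies; homoscedastic,
Gaussian residuals on the log₁₀ scale (i.e., multiplicative scatter);
and no systematic difference between CT-derived and scale-weighed lung
weights beyond that scatter.

### Fitting

`ExponentialIndexRegressor` fits ordinary least squares of log₁₀(LWI)
on BW (statsmodels OLS); `a` is the back-transformed intercept and `b`
the slope. Fitting on the log scale is the default because the model's
residual statistics (RMSE/MAE ≈ 0.05–0.07) are defined on log₁₀(LWI);
a nonlinear least-squares fit on the natural g/kg scale is available
with `scale="natural"` for sensitivity analysis, with Wald CIs from the
curve-fit covariance. Parameter CIs are two-sided 95% t-intervals from
the regression covariance, the `a` interval back-transformed from the
intercept interval.

The band curves pair the upper bounds of `a` and `b` (upper band) and
the lower bounds (lower band). This is a *parameter-wise* band — the
construction used for the published band curves — not a pointwise
prediction or confidence band; it brackets the point curve everywhere
but its coverage is not exactly 95% at any given BW. The distinction is
recorded in the fit metadata and matters for the error-bound analysis
below, which deliberately evaluates errors at these endpoint curves.

### Splitting, evaluation, cross-validation

`split_cohort` partitions a cohort at a training fraction f with
training size floor(n·f), clamped so both parts are non-empty; at
n = 177 and f = 0.8 this gives the canonical 141/36 partition (a
half-rounding rule would give 142/35 and cannot reproduce it). The
permutation comes from `numpy.random.default_rng(seed)`, so partitions
are deterministic given the seed. `evaluate` reports RMSE and MAE of
log₁₀ residuals; `cross_validate` is standard k-fold (sklearn `KFold`,
shuffled, seeded), defaulting to k = 5 — a conventional choice, since
no particular fold count is canonical for this analysis.

## Quantitative-CT densitometry

CT attenuation in lung is treated as a linear gas/tissue mixture:
−1000 HU pure gas, 0 HU water-equivalent tissue, +1000 HU bone. A voxel
at CT number HU has tissue fraction 1 − HU/−1000, clamped to [0, 2];
lung weight is the masked sum of tissue fraction × voxel volume
(mm³ → cm³) at a tissue density of 1 g/cm³, which the 0-HU ↔ tissue
anchor implies. Consequences of these choices:

- Voxels below −1000 HU (scanner noise) count as pure gas; above
  +1000 HU as the bone endpoint. Clamped-voxel counts are logged —
  the handling of out-of-range values is this package's choice, as no
  standard exists.
- Gas volume uses the complementary gas fraction clamped to [0, 1] and
  tissue volume is defined as masked volume − gas volume, so the two
  always partition the masked region; voxels above 0 HU add weight
  (fraction > 1) but no extra volume.
- Masks are caller-supplied. Excluding airways, vessels and bone is a
  segmentation problem outside scope; the weight of whatever is masked
  is computed faithfully.

`make_phantom` builds uniform-density volumes with a closed-form weight
(jitter is mean-centred so the analytic value is exact), used by the
self-consistency tests.

## Bland–Altman agreement

Differences are fixed as measured − expected, so a negative bias means
measurement below the model's expectation. Bias = mean difference;
limits of agreement = bias ± 1.96·sd (conventional normal multiplier,
not a t quantile); 95% CIs use t quantiles with n−1 df, SE = sd/√n for
the bias and the standard large-sample approximation SE = sd·√(3/n) for
each LOA. These exact choices regenerate the published validation
intervals from the published n, bias and LOA, which is how they were
pinned down. No difference-vs-mean trend test is performed (none is
part of the reference analysis); pair means are exported for plotting.

## Edema normalization and error bounds

`damage_ratio` is measured/expected lung weight; equal true damage
yields equal ratios regardless of animal size.
`naive_normalization_discrepancy` quantifies the artifact this removes:
with both animals' lungs scaled by the same damage factor, the g/kg
indices differ by (idx₁ − idx₂)/idx₁ — algebraically independent of the
damage factor, and ≈ 40% for 20 vs 40 kg under the reference equation.

`error_bounds_curve` asks how wrong a damage ratio can be if the
expected weight is taken from a CI band curve instead of the point
model: at each BW the true damaged weight is factor × point prediction,
and the signed error ((measured/expected_used) − factor)/factor is
evaluated with the upper band as expected weight (worst
underestimation) and the lower band (worst overestimation). Maxima are
evaluated at the band endpoint curves only — not by optimizing over the
joint parameter confidence region — matching how the published bounds
were derived. Negative = underestimation. Grid points outside 16–52 kg
are computed but logged, since the model is unvalidated there and is
expected to underestimate in heavier animals as lung growth plateaus.

## Synthetic cohorts

`generate_cohort` emulates the study population the reference equation
was derived from: n animals (default 177), body weights uniform on
16.5–52 kg, log₁₀(LWI) = log₁₀(a) + b·BW + ε with ε ~ N(0, σ) and
σ = 0.068 — the residual RMSE of the published training fit. Noise is
multiplicative (Normal on log₁₀) rather than additive: that is the
scale on which the published residual statistics are defined, and it
guarantees positive lung weights. Seeds are mandatory; there is no
global random state.

What the generator does *not* emulate: the multi-study provenance (12
source studies with possible batch structure), the real — unpublished —
body-weight distribution (uniform is an assumption), any CT-vs-scale
method difference in dispersion (a single noise level is used, as no
method-specific dispersion was reported), and any model misspecification
(synthetic cohorts are exactly exponential). Passing tests therefore
demonstrate that the estimators recover what they claim under the
model's own assumptions — not that the exponential form is correct for
real pigs.

## Numerical choices and problem sizes

- Zero-noise cohorts reproduce the generating curve to ~1e−12 relative;
  fits on them recover parameters to 1e−6 (a) / 1e−9 (b).
- Degenerate inputs fail loudly: < 3 animals, zero body-weight
  variance, non-positive weights, mismatched array shapes, empty
  cohorts. An empty lung mask returns an all-zero measurement with a
  warning rather than an error, since empty masks arise legitimately
  from upstream segmentation.
- Monte-Carlo checks use 100–120 replicate cohorts of n = 141 at
  σ = 0.068 — enough that the mean recovered prefactor has a standard
  error ≈ 0.5%, well inside the 2% check band, while keeping the whole
  suite under a couple of minutes on one CPU.
- The brute-force fit oracle is a 201×201 grid over (log₁₀ a, b)
  centred on the closed-form solution (half-widths 0.05 and 0.005);
  agreement is asserted to grid resolution.

## Known limitations

- The parameter-wise CI band is conservative relative to a pointwise
  prediction band; error bounds derived from it are "maximal" in the
  band-endpoint sense only.
- The reference applies to female domestic pigs, 16–50 kg; other
  breeds, sexes and weights are out of scope.
- Densitometric weight is only as good as the supplied mask; pleural
  effusion, airway gas trapped outside the mask, or included vessels
  bias it in the obvious directions.
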