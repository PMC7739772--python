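# Methods

## Model

The core model is the continuous linear-plateau (hinge) regression of an
outcome y (100-m season-best time, seconds) on a muscle-size predictor x:

    y_i = β₀ + β₁·min(x_i, τ) + ε_i,   ε_i ~ N(0, σ²) i.i.d.

Below the change-point τ the outcome changes linearly with slope β₁
(negative in all study-like scenarios: thicker muscle, faster time);
at τ the mean function becomes exactly flat, continuously.  The plateau
slope is fixed at zero by construction — a free-slope two-phase
(segmented) model is deliberately out of scope, as the scientific claim
being modelled is saturation, not a slope change.

### Fitting

For fixed τ the model is linear in (β₀, β₁), so τ is profiled: for each
candidate on a uniform grid over [min(x), max(x)] (1001 points by
default, endpoints included) the OLS solution on the transformed
predictor z = min(x, τ) is computed in closed form, and the τ minimizing
SSE is selected.  Ties take the smallest τ, making the fit deterministic.
Candidates for which z is numerically constant (τ at the lower data
edge) fall back to the intercept-only fit.  The grid step,
(max−min)/1000, is far below the measurement precision of ultrasound
thickness readings, so no continuous refinement is attempted.  Grid
resolution is configurable.

### Model choice

The hinge competes with the simple line via the Gaussian
profile-likelihood AIC, n·ln(SSE/n) + 2k, with k = 3 for the line
(intercept, slope, error SD) and k = 4 for the hinge (adds τ).  The same
formula family is used for both models so the dropped 2π constants
cancel.  A change-point is declared present iff the hinge AIC is
smaller — the sign of ΔAIC, with no additional evidence threshold.
Because the grid contains τ = max(x), the hinge nests the line and its
SSE never exceeds the linear SSE; a ΔAIC of exactly +2 is the
no-evidence limit.  When either SSE is numerically zero (relative to
total y variation, threshold 1e-15) the AIC is −∞-degenerate and the
decision falls back to comparing SSEs, flagged in the output.

### Uncertainty and stability

The sampling distribution of τ̂ at n = 14 is asymmetric and poorly
approximated by normal theory, so the CI is a nonparametric case
bootstrap: participants (x, y pairs) resampled with replacement B = 2000
times, hinge refitted on each, percentile interval at
(1−level)/2 and 1−(1−level)/2.  Resamples with fewer than 4 distinct
predictor values cannot support a hinge and are redrawn (counted, capped
at 10·B attempts).  Stability is assessed by leave-one-out refits: n
folds, each omitting one participant, reporting the per-fold τ̂, their
range and SD, and whether the AIC preferred the hinge in every fold;
degenerate folds are flagged by participant id, never dropped.

## Correlations

Spearman's ρ is computed on mid-ranks (average ranks for ties).  The
two-sided p-value is exact — full enumeration of all n! rank
permutations — for n ≤ 9 without ties, where enumeration is cheap and
the t approximation is at its weakest; otherwise the usual
t = ρ·√((n−2)/(1−ρ²)) approximation with n−2 df.  The method used is
recorded on the result.  Verbal effect-size labels follow Mukaka's rule
with lower-inclusive |ρ| edges 0.30/0.50/0.70/0.90
(negligible/low/moderate/high/very high); lower-inclusive so that
ρ = 0.30 is "low".  Significance is α = 0.05, two-sided, stored in the
analysis config.  A multiple-regression utility (OLS with intercept,
standard errors, t p-values, R²) is provided for completeness; it plays
no role in the change-point decision.

## Allometric normalization

Linear muscle dimensions are divided by body mass^(1/3) — the exponent
for a length under geometric similarity — giving mm/kg^(1/3) or
cm/kg^(1/3); the PM area is divided the same way for report consistency.
The transform is a plain elementwise ratio, not regression-based
allometry, and is exactly invertible (values·mass^(1/3) recovers the
input to 1e-12 relative tolerance).  Units are otherwise never
converted: TA stays mm, MM cm, PM cm², mirroring the mixed-unit
convention of the field.

## Synthetic cohorts

The generator emulates the study conditions: n = 14; predictor drawn
from a normal with the published moments (TA 4.36 ± 0.72 mm, truncated
to (2.8, 6.0) mm; MM 3.99 ± 0.48 cm, truncated to (2.6, 5.4) cm — the
bounds keep draws physically plausible at roughly ±2.2 SD), outcome from
the hinge with τ = 4.70 mm (TA) or 3.84 cm (MM), residual SD
σ = 0.2 s, and body mass N(65.6, 4.8²) kg truncated positive.  The
published intercept and slope do not exist, so they are calibration
choices: β₀ = 14.3 s, β₁ = −0.7 s/mm for TA puts the plateau at
β₀ + β₁τ ≈ 11.0 s, the published mean sprint time; MM uses β₁ = −1.05
s/cm, chosen so β₁·SD(x) ≈ −0.50 s per predictor SD matches the TA
scenario, with β₀ = 15.0 s.  σ = 0.2 s leaves the marginal sprint-time
SD near the published 0.48 s once the hinge's systematic spread is
added.  Truncated normals are drawn by rejection sampling from a single
seeded stream with a fixed draw order (predictor, noise, mass, age,
height, PM, the non-driving muscle), so cohorts are bit-reproducible
from the seed; adding a field is by policy a breaking change.

What the generator does **not** emulate: any correlation between
anthropometric fields (height–mass, TA–MM ...) — no joint covariance is
published, so all non-driving columns are independent; measurement error
in x; non-Gaussian residuals; and only one muscle drives the outcome per
cohort.  Passing tests therefore demonstrate correctness of the
machinery under the assumed generative model, not that real sprint
cohorts satisfy those assumptions.

## Operating characteristics

`operating_characteristics()` replicates the whole pipeline over many
generated cohorts.  Problem sizes used by the shipped drivers and
checks: 500 replicates for selection rate and recovery (median |τ̂−τ|,
median slope bias), and 200–300 outer replicates × 300–400 inner
bootstrap resamples for CI coverage — sizes at which the Monte-Carlo
standard error of a selection rate is ~2 points and of a coverage
estimate ~1.5 points.  Measured at these sizes: the AIC sign rule
detects the true TA-scenario change-point in roughly 72–76% of cohorts,
prefers the hinge in ~12–15% of matched linear-null cohorts, recovers τ
with median absolute error ~0.18 mm, and the nominal 95% percentile CI
covers the true τ ~93–95% of the time.  The detection rate is a genuine
property of n = 14 at σ = 0.2: about one cohort in ten has two or fewer
points beyond τ, where the plateau is essentially unidentifiable.

## Pipeline conventions

Descriptive 95% CIs of the mean use the t quantile with n−1 df (the
convention that reproduces the published descriptive-table shape at
n = 14).  Sub-seeds for every stochastic stage derive from
SeedSequence([master_seed, crc32("stage:predictor:raw|norm")]), so
reports are byte-identical across runs and per-predictor draws are
independent of the predictor list.  The bootstrap and LOOCV are
recomputed from scratch on normalized series rather than transforming
raw-series results, since normalization changes the resampling geometry.
Spearman's precondition n ≥ 4 is enforced; correlation of shorter series
is refused rather than extrapolated.

## Known limitations

- The hinge grid search is O(n·grid) per fit; exactness, not speed, is
  the design goal, though study-scale fits take ~0.1 ms.
- The AIC sign rule at n = 14 is underpowered (see above); absence of a
  detected change-point is weak evidence of absence.
- Percentile bootstrap intervals for change-points can undercover when
  τ sits near the data edge; coverage was verified only under the
  calibrated scenarios.
- LOOCV measures stability, not out-of-sample error; with n = 14 a
  single influential participant can still move τ̂ by several grid
  steps.
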