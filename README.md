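# sprintcp

Change-point ("biphasic") regression analysis of 100-m sprint performance
against deep trunk muscle size, built for sports-science and biostatistics
work on small athlete cohorts.

## The problem

In a cohort of collegiate male sprinters (n = 14), season-best 100-m time
was related to the size of three deep trunk stabilizers: psoas major
cross-sectional area (PM, cm², L4–L5, left+right sum), transversus
abdominis thickness (TA, mm) and multifidus thickness (MM, cm).  The
relationship of interest is not a straight line: sprint time falls as the
muscle gets thicker *up to a point*, then plateaus.  The model is the
continuous linear-plateau (hinge) regression

```
y = β₀ + β₁·min(x, τ) + ε,   ε ~ N(0, σ²)
```

with change-point τ.  For each candidate τ on a uniform grid over the
observed predictor range, (β₀, β₁) are profiled out by closed-form OLS on
the transformed predictor min(x, τ); the grid search is therefore exact
per candidate and fully deterministic (smallest τ wins SSE ties).  A
change-point is declared present when the hinge's Gaussian AIC,
`n·ln(SSE/n) + 2k` with k = 4, is smaller than the simple line's (k = 3).
Uncertainty in τ comes from a nonparametric case bootstrap (percentile
interval, B = 2000), stability from leave-one-out refits, correlations
from Spearman's ρ (exact permutation p for n ≤ 9 without ties, t
approximation otherwise) with Mukaka's verbal bands, and body-size
effects are removed by allometric normalization x/mass^(1/3).

No per-participant data are published for the original cohort, so the
package includes a seeded synthetic-cohort generator calibrated to the
published marginal moments, and every analysis here runs on such cohorts.

## Worked example

```
$ sprintcp simulate --n 14 --seed 1 --out cohort.csv
$ sprintcp analyze --input cohort.csv --seed 1 --out report.json
```

or, running the numbered analysis scripts (they write their tables under
`results/`):

```
$ python analysis/01_simulate_cohorts.py
TA-mode cohort (seed 1): n=14, predictor 4.46 +/- 0.45 (calibration 4.36 +/- 0.72),
sprint time 11.15 +/- 0.34 s -> cohort_ta.csv
$ python analysis/02_descriptives_correlations.py
Spearman correlations of 100-m time with muscle size:
  pm_csa_cm2       rho=-0.349  p=0.221  (low)
  ta_thickness_mm  rho=-0.679  p=0.008  (moderate)
  mm_thickness_cm  rho=-0.182  p=0.533  (negligible)
$ python analysis/03_changepoint_fits.py
TA raw        change-point 4.38 mm (95% CI 3.95-5.01), dAIC=-0.13 (present); ...
TA normalized change-point 1.08 mm/kg^(1/3) (95% CI 0.98-1.22), dAIC=-2.87 (present); ...
```

Reading this: on a synthetic cohort whose true change-point is 4.70 mm,
the TA column shows a moderate negative Spearman correlation with sprint
time (ρ = −0.68, p < 0.01), the hinge model beats the straight line by
AIC (ΔAIC < 0), and the estimated change-point is 4.38 mm with a 95%
percentile-bootstrap interval of 3.95–5.01 mm.  The other two muscle
columns are filled independently of the outcome and act as negative
controls.  `analysis/04_operating_characteristics.py` replicates the
whole procedure 500 times: the AIC sign rule detects a true change-point
in ~72% of cohorts at this noise level, falsely prefers the hinge in
~12% of matched linear-null cohorts, and the nominal 95% bootstrap CI
covers the true τ ~93% of the time.

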