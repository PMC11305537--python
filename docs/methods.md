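# Methods

## The problem

An interrupted time series (ITS) design estimates the effect of a shock — a
policy change, a school closure — by comparing the observed post-shock series
against the pre-shock trend extrapolated forward. With long series and a
single intervention this is well-trodden ground; the setting here is the
uncomfortable one practitioners actually face with pupil tracking data:
six to twenty measurement occasions, a second intervention landing late in
the series, and effect sizes that are a small fraction of normal growth.
The package quantifies, by Monte Carlo simulation, when such a design has
adequate power and what under- or over-specifying the model costs in power,
bias and precision.

## Data-generating process (`itspower.dgp`)

Scores are generated per measurement occasion `t = 1..T` as

```
Y = mu(t) + b + e,    b ~ N(0, 25),   e ~ N(0, 25)
```

where the mean function on the centered time axis
`c = t − (T/2 + 0.5)` is

```
mu = beta0 + beta1*c + X1*(beta_step + beta_slope*c) + X2*beta_step2
```

with `beta0 = 170 + 16.5*(T/2 − 0.5)` (the baseline level of 170 score
units at the first occasion propagated to the intervention midpoint),
`beta1 = 16.5` score units per occasion (one school year's growth between
occasions), and intervention effects expressed as a fraction *e* of that
slope, applied negatively: `beta_step = beta_slope = −e·16.5` for the shapes
that include them, and a second step at 50% of the first for the two-step
shape. `X1` flags the last `T/2` occasions (the first intervention always
falls exactly between the two middle occasions, so centered times are
half-integers and the step coefficient is the jump at `c = 0`);
`X2` flags occasions strictly after `k = round-half-up(0.75·T)`.

Conventions worth noting, since each had genuine alternatives:

- **Second-intervention boundary.** "75% of the series" does not place the
  boundary on an occasion for most `T`; round-half-up was chosen and is
  applied uniformly. It produces the alternating between/after occasion
  parity (2/1, 2/2, 3/2, 3/3, …) that drives the oscillating underfit bias
  pattern (see `analysis/03_misfit_bias.py`). Other roundings shift the
  phase of that pattern but not its character.
- **Additive second-step dummy.** The `X2` coefficient is the *incremental*
  second step, so the generative value is stored directly; the total level
  change since the second intervention is exposed on fit results as
  `second_step_total_contrast` (the sum of the two step coefficients).
- **Sampling mode.** `cross_sectional` (default) draws the baseline
  deviation `b` independently for every record, matching a testing system
  that samples a fresh cross-section each occasion; `longitudinal` draws `b`
  once per subject and reuses it, giving within-subject correlation. The
  default reproduces exact nominal type-I error for pooled OLS, which is the
  calibration property the simulation rests on; under the longitudinal mode
  pooled OLS standard errors are misspecified by construction, which is
  precisely the kind of sensitivity the option exists to explore.
- **Negative effect sizes** are accepted and simply flip every intervention
  coefficient's sign; power is unaffected (symmetry of the two-sided test),
  which the suite verifies.

With both variances set to zero the generator is exact: every score lies on
`mu` to machine precision, which the tests use for exact-recovery oracles.

## Models (`itspower.models`)

Five OLS design variants over the terms
{intercept, T, X1, T·X1, X2, T·X2, T²}:

| name | terms |
|---|---|
| `basic` | 1, T, X1, T·X1 |
| `two_intervention_steps` | 1, T, X1, X2, T·X1 |
| `two_intervention_full` | 1, T, X1, T·X1, X2, T·X2 |
| `quadratic` | 1, T, X1, T·X1, T² |
| `combined` | 1, T, X1, T·X1, X2, T·X2, T² |

`two_intervention_steps` carries a single shared post-intervention slope —
with at most two occasions between the interventions a separate second slope
is not estimable in the short-series regime, so the paired-comparison
catalog uses this form; the full form remains available.

Estimation is ordinary least squares via the economy QR factorization, with
classical homoskedastic standard errors `sigma² (X'X)⁻¹` and two-sided
p-values from the t distribution on `N − p` degrees of freedom. No robust or
cluster correction is applied: the cross-sectional DGP satisfies the
classical assumptions exactly, and the point of the study is the behaviour
of the plain pooled-OLS workflow. Rank deficiency is detected from the R
diagonal at a relative threshold of 1e-10 and raised as
`SingularDesignError` naming the collinear columns. The solver is checked
against statsmodels OLS (estimates, SEs, t, p) on hundreds of random
instances in the test suite.

Fits use individual records, not occasion means, so the cohort size enters
through `N = n·T`. For a balanced panel the two give identical point
estimates and (up to the dof used for `sigma²`) the same standard errors;
record-level fitting is what the pooled workflow being studied does.

## Monte Carlo engine (`itspower.montecarlo`)

A *cell* is (scenario, shape, model, reps). Per replication `r`, a panel is
generated from seed `SeedSequence(base_seed, T, n, effect, shape, mode, r)`
— deliberately independent of the fitted model, so all models fitted to one
cell see identical panels and model contrasts are paired. Any single
replication is reproducible in isolation from its seed tuple.

Within a cell the design matrix never changes, so it is factorized once and
all replications are fitted in one batched solve; the suite asserts
equality with the naive per-replication refit (to ~1e-12; the batched and
single-column BLAS paths differ in the last ulp).

Performance criteria per coefficient, against the generative value (zero
for any term absent from the DGP, making its "power" a type-I error rate):

- **power** — share of replications with two-sided p strictly below alpha
  (default 0.05);
- **bias** — `|mean(estimate) − truth|`, the absolute value taken *after*
  averaging, so sampling scatter cancels and what remains is systematic;
- **precision** — mean model-based standard error, with the empirical SD of
  the estimates retained alongside as a diagnostic (for right-fit cells the
  two agree; divergence flags misspecification).

Replications default to 1000; the shipped analysis and acceptance runs use
200–1000 depending on what the quantity needs (a binomial proportion at
p≈0.05 needs 1000 draws for a ±0.02 three-SE band; a ≥0.80 threshold check
is comfortable at 500). Singular fits are skipped and counted, and a cell
aborts if more than 1% fail — with these designs none do.

The default pairing catalog is the study's six rows: `basic` as right fit
(step+slope data), overfit (step-only and slope-only data), and underfit
(two-step data); `two_intervention_steps` as the corrected two-step fit; and
`quadratic` as trend overfit on step+slope data.

## Reporting (`itspower.reporting`)

Results are a long-format table (scenario × model × coefficient × metric),
exported as CSV with a YAML echo of the run configuration; reruns are
byte-identical. `heatmap_grid` pivots a slice into the (subjects ×
timepoints) matrix behind the study's heatmaps (missing cells stay NaN);
`minimum_requirements` extracts, per (shape, model, coefficient, effect),
the Pareto-minimal (n, T) pairs whose power meets the adequacy threshold of
0.80 — the "minimum design" a planner would read off. Frontier logic is
property-tested against brute-force dominance enumeration. PNG heatmaps are
optional cosmetics; the CSVs are canonical.

## What the simulation does and does not show

The generator is faithful to its stated model: independent Gaussian noise,
constant growth, constant cohort size, equally spaced occasions, effects
exactly proportional to the slope. Real tracking data have none of these
guarantees — heterogeneous growth, cohort drift, missingness, serial
correlation at the occasion level — so passing results certify the design's
behaviour *under the stated assumptions*, not under violations of them.
In particular, occasion-level shocks shared across subjects (a hard exam
year) would inflate type-I error far beyond anything simulated here, and
the longitudinal mode shows pooled OLS SEs are already optimistic under
within-subject correlation. Multilevel, autoregressive and growth-curve
extensions are out of scope by design.

Two robust qualitative findings the analysis scripts reproduce: the power
to detect a step change is driven mainly by the cohort size, while the
power for a slope change is driven by the series length; and
misspecification is not symmetric — underfitting a second step biases the
first step upward (toward zero, for negative shocks) and the slope change
downward, while overfitting an unneeded quadratic term costs the slope
change most of its power at small `T`.

## Numerical choices

- Half-integer centered times make `X1` and the intercept exactly
  orthogonal; conditioning is excellent for every design in the catalog.
- Zero-variance panels produce zero residual variance; t statistics are
  reported as ±inf with p = 0, which exact-recovery tests rely on.
- Seeds are 32-bit-safe SeedSequence tuples; effect sizes enter the key as
  `round(|e|·10⁴)` plus a sign flag, so grid effect values are distinct
  stream keys.
- Frontier comparison uses strict `power > threshold` with threshold 0.80
  (configurable); dominance is weak inequality in both coordinates.
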