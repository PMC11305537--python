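# itspower

Monte Carlo power, bias and precision analysis for **interrupted time
series (ITS) designs with few time points**.

ITS designs estimate the effect of a shock — a lockdown, a policy change —
by fitting a segmented regression to a series of outcomes and testing
whether the level (*step change*) or trend (*slope change*) shifts at the
intervention. The method is well understood for long series; this package
targets the regime education and public-health researchers actually work
in: 6–20 measurement occasions, cohorts of 100–1500 subjects per occasion,
effects worth a few percent of normal growth, and sometimes a second
intervention arriving late in the series.

The core model on the centered time axis `T` (zero at the intervention) is

```
Y_t = β0 + β1·T + β2·X_t + β3·T·X_t + ε_t
```

where `X_t` indicates post-intervention occasions, `β2` is the step change
and `β3` the slope change. Variants add a second-step dummy (`X2`), a
separate post-second-intervention slope (`T·X2`), and/or a quadratic trend
(`T²`). The package

- **simulates** score panels from a growth model calibrated to pupil
  tracking data (baseline `N(170, 25)`, growth 16.5 points per occasion,
  occasion noise `N(0, 25)`, negative shocks sized as a fraction of the
  slope) under four intervention shapes;
- **fits** five segmented-regression variants by pooled OLS with a
  factorized design shared across replications;
- **aggregates** empirical power, absolute bias and precision per
  coefficient over a scenario grid (8 series lengths × 8 cohort sizes × 6
  effect sizes = 384 scenarios by default, with right-fit, overfit and
  underfit model/data pairings);
- **reports** heatmap-ready grids and the Pareto-minimal (n, T)
  combinations achieving adequate power (> 0.80).

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

One simulation cell — step+slope shock at 15% of the slope, 1100 subjects
per occasion, 12 occasions, 500 replications:

```
$ itspower cell --shape step_slope --model basic -T 12 -n 1100 -e 0.15 \
    --reps 500 --seed 1
{
  "scenario": "T12_n1100_e0.15_step_slope",
  "model": "basic",
  "reps": 500,
  "failures": 0,
  "power":         { ..., "X1": 1.0,      "T*X1": 1.0 },
  "bias":          { ..., "X1": 0.00234,  "T*X1": 0.00114 },
  "precision":     { ..., "X1": 0.24872,  "T*X1": 0.07205 },
  "mean_estimate": { ..., "X1": -2.47734, "T*X1": -2.47614 },
  "empirical_sd":  { ..., "X1": 0.26743,  "T*X1": 0.07044 }
}
```

The true step and slope change are both `−0.15 × 16.5 = −2.475`; the mean
estimates land on them to three decimals (bias ≈ 0.002 score units), the
model-based standard error (precision, 0.249 for the step) matches the
empirical SD of the estimates (0.267), and every replication rejects the
null for both coefficients, so this design comfortably clears the 0.80
adequacy threshold.

The numbered drivers under `analysis/` run the full study pieces and write
tables under `results/`:

```
python analysis/01_calibration.py     # type-I error of null coefficients ≈ 0.05
python analysis/02_power_grid.py      # power/bias/precision grid + frontiers
python analysis/03_misfit_bias.py     # underfit bias pattern, overfit power loss
```

Library use mirrors the CLI:

```python
from itspower import ScenarioSpec, run_cell

cell = run_cell(ScenarioSpec(12, 1100, 0.15, shape="step_slope"),
                model="basic", reps=500, base_seed=1)
cell.power["X1"]        # 1.0
cell.precision["T*X1"]  # 0.072
```

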