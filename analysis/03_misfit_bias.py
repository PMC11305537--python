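#!/usr/bin/env python
"""What model misspecification does to ITS estimates.

Two analyses:

1. Underfit — the basic single-intervention model fitted to data that also
   contain a second, half-sized step.  The fitted step absorbs part of the
   late extra drop into the slope term: the (negative) step is estimated too
   high, the slope change too low, and the step bias follows an alternating
   pattern in the series length driven by how many occasions fall between
   and after the two interventions.  The asymptotic bias (projection of the
   true mean onto the misspecified design) is computed exactly alongside the
   Monte Carlo estimate.

2. Overfit — adding a quadratic trend term to data with a plain step+slope
   intervention: the slope-change coefficient loses most of its power and
   its standard error inflates.

Writes results/misfit_bias.csv and results/overfit_power.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from itspower import (
    ScenarioSpec,
    build_design,
    intervention_schedule,
    run_cell,
    true_coefficients,
)
from itspower.dgp import occasion_means


def projected_step(T: int, effect: float) -> float:
    s = ScenarioSpec(T, 1, effect, shape="two_steps_slope")
    X = build_design(intervention_schedule(T, "two_steps_slope"), "basic")
    return float(np.linalg.lstsq(X, occasion_means(s), rcond=None)[0][2])


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--reps", type=int, default=300)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    effect = 0.15
    rows = []
    for T in (6, 8, 10, 12, 14, 16, 18, 20):
        s = ScenarioSpec(T, 700, effect, shape="two_steps_slope")
        cell = run_cell(s, model="basic", reps=args.reps, base_seed=args.seed)
        true = true_coefficients(s)
        k = intervention_schedule(T, "two_steps_slope").second_boundary_index
        rows.append({
            "timepoints": T,
            "between_occasions": k - T // 2,
            "after_occasions": T - k,
            "true_step": true.beta_step,
            "asymptotic_step": projected_step(T, effect),
            "mc_mean_step": cell.mean_estimate["X1"],
            "mc_step_bias": cell.bias["X1"],
            "true_slope_change": true.beta_slopechange,
            "mc_mean_slope_change": cell.mean_estimate["T*X1"],
        })
    underfit = pd.DataFrame(rows)
    underfit.to_csv(args.outdir / "misfit_bias.csv", index=False)
    print("Underfit (basic model on two-step data, e=0.15, n=700):")
    print(underfit.round(3).to_string(index=False))
    print(
        "\nThe fitted step sits above the true step at every T (signed "
        "over-estimation), the slope change below it, and the asymptotic "
        "bias alternates with the between/after occasion parity while "
        "declining overall.\n"
    )

    rows = []
    for n in (100, 300, 700):
        s = ScenarioSpec(8, n, 0.05, shape="step_slope")
        basic = run_cell(s, model="basic", reps=args.reps, base_seed=args.seed)
        quad = run_cell(s, model="quadratic", reps=args.reps, base_seed=args.seed)
        rows.append({
            "subjects": n,
            "slope_power_basic": basic.power["T*X1"],
            "slope_power_quadratic": quad.power["T*X1"],
            "slope_se_basic": basic.precision["T*X1"],
            "slope_se_quadratic": quad.precision["T*X1"],
        })
    overfit = pd.DataFrame(rows)
    overfit.to_csv(args.outdir / "overfit_power.csv", index=False)
    print("Overfit (quadratic trend added to step+slope data, T=8, e=0.05):")
    print(overfit.round(3).to_string(index=False))
    print(
        "\nThe unneeded quadratic term inflates the slope-change standard "
        "error several-fold and erases most of its power."
    )


if __name__ == "__main__":
    main()
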