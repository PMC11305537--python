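#!/usr/bin/env python
"""Power, bias and precision over a reduced scenario grid.

Runs all six model/data pairings (right fits, overfits, the two-step
underfit and its corrected two-intervention fit) over a thinned version of
the full grid — every other series length, half the cohort sizes, all six
effect sizes — and exports the long-format results plus the adequate-power
(> 0.80) frontier per coefficient and effect size.

The full-resolution grid (8 x 8 x 6 scenarios x 6 pairings at 1000
replications) is the same call with the default RunConfig; this reduced run
keeps the turnaround at a few minutes on one core.
"""

import argparse
from pathlib import Path

from itspower import RunConfig, export_report, minimum_requirements, run_grid
from itspower.reporting import load_results

REDUCED = dict(
    timepoints=(6, 10, 14, 18),
    subjects=(100, 500, 1100, 1500),
    effects=(0.01, 0.025, 0.05, 0.10, 0.15, 0.30),
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--reps", type=int, default=200)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/power_grid"))
    parser.add_argument("--full", action="store_true",
                        help="run the full 8x8x6 grid instead of the reduced one")
    parser.add_argument("--resume", action="store_true")
    args = parser.parse_args()

    grid_axes = {} if args.full else REDUCED
    cfg = RunConfig(reps=args.reps, base_seed=args.seed, **grid_axes)

    existing = None
    results_path = args.out / "results.csv"
    if args.resume and results_path.exists():
        existing = load_results(results_path)
        print(f"resuming from {len(existing)} existing rows")

    table = run_grid(cfg, existing=existing, progress=True)
    paths = export_report(table, args.out, config=cfg)

    power = table[table["metric"] == "power"]
    n_cells = len(power) // power["coefficient"].nunique() or 1
    print(f"\n{len(table)} result rows over {power['scenario_id'].nunique()} "
          f"scenario cells; artifacts: {sorted(paths)}")

    for entry in minimum_requirements(table):
        if entry.coefficient in ("X1", "T*X1", "X2") and entry.minimal_pairs:
            print(
                f"adequate power for {entry.coefficient:5s} "
                f"[{entry.shape}/{entry.model}, e={entry.effect_size:g}]: "
                f"minimal (n, T) = {list(entry.minimal_pairs)}"
            )


if __name__ == "__main__":
    main()
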