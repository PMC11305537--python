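"""Aggregation of simulation result tables: heatmap grids and power frontiers.

The canonical artifact is the long-format results CSV (one row per
scenario x model x coefficient x metric).  This module pivots slices of it
into dense (subjects x timepoints) grids — the tabular form behind the
study's heatmaps — and extracts *minimum-requirement frontiers*: the
Pareto-minimal (n, T) combinations at which a coefficient's empirical power
reaches the adequacy threshold (0.80 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montecarlo import RESULT_COLUMNS, RunConfig

__all__ = [
    "FrontierEntry",
    "heatmap_grid",
    "minimum_requirements",
    "export_report",
    "load_results",
    "DEFAULT_POWER_THRESHOLD",
]

logger = logging.getLogger("itspower")

DEFAULT_POWER_THRESHOLD = 0.80


@dataclass(frozen=True)
class FrontierEntry:
    """Pareto-minimal (subjects, timepoints) pairs reaching adequate power."""

    shape: str
    model: str
    coefficient: str
    effect_size: float
    threshold: float
    minimal_pairs: tuple[tuple[int, int], ...]  # (n_subjects, n_timepoints)


def _slice(
    table: pd.DataFrame,
    shape: str,
    model: str,
    coefficient: str,
    metric: str,
    effect_size: float,
) -> pd.DataFrame:
    mask = (
        (table["shape"] == shape)
        & (table["model"] == model)
        & (table["coefficient"] == coefficient)
        & (table["metric"] == metric)
        & np.isclose(table["effect"], effect_size)
    )
    return table[mask]


def heatmap_grid(
    table: pd.DataFrame,
    shape: str,
    model: str,
    coefficient: str,
    metric: str = "power",
    effect_size: float = 0.15,
) -> pd.DataFrame:
    """Dense (subjects x timepoints) grid for one results slice.

    Axes ascend; cells absent from the table are NaN (flagged, never
    imputed).  Raises if the slice is empty, naming the requested keys.
    """
    sub = _slice(table, shape, model, coefficient, metric, effect_size)
    if sub.empty:
        raise KeyError(
            "no results for slice "
            f"(shape={shape}, model={model}, coefficient={coefficient}, "
            f"metric={metric}, effect={effect_size})"
        )
    grid = sub.pivot_table(
        index="subjects", columns="timepoints", values="value", aggfunc="first"
    )
    return grid.sort_index(axis=0).sort_index(axis=1)


def _pareto_minimal(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pairs not dominated by another pair with both coordinates <=."""
    out = []
    for p in pairs:
        if not any(
            q != p and q[0] <= p[0] and q[1] <= p[1] for q in pairs
        ):
            out.append(p)
    return sorted(set(out))


def minimum_requirements(
    table: pd.DataFrame, threshold: float = DEFAULT_POWER_THRESHOLD
) -> list[FrontierEntry]:
    """Per (shape, model, coefficient, effect): minimal adequate (n, T) pairs.

    A pair qualifies when its cell's empirical power strictly exceeds the
    threshold (adequate power is "> 0.80"); the frontier keeps only pairs not
    dominated in both coordinates.  Slices with no adequate cell yield an
    entry with an empty frontier.
    """
    power = table[table["metric"] == "power"]
    entries = []
    group_cols = ["shape", "model", "coefficient", "effect"]
    for (shape, model, coef, effect), sub in power.groupby(group_cols, sort=True):
        adequate = sub[sub["value"] > threshold]
        pairs = list(
            zip(adequate["subjects"].astype(int), adequate["timepoints"].astype(int))
        )
        entries.append(
            FrontierEntry(
                shape=shape,
                model=model,
                coefficient=coef,
                effect_size=float(effect),
                threshold=threshold,
                minimal_pairs=tuple(_pareto_minimal(pairs)),
            )
        )
    return entries


def frontier_frame(entries: list[FrontierEntry]) -> pd.DataFrame:
    rows = [
        {
            "shape": e.shape,
            "model": e.model,
            "coefficient": e.coefficient,
            "effect": e.effect_size,
            "threshold": e.threshold,
            "subjects": n,
            "timepoints": t,
        }
        for e in entries
        for (n, t) in e.minimal_pairs
    ]
    return pd.DataFrame(
        rows,
        columns=["shape", "model", "coefficient", "effect", "threshold",
                 "subjects", "timepoints"],
    )


def load_results(path) -> pd.DataFrame:
    """Read a results CSV back into the canonical long-format table."""
    return pd.read_csv(path)[RESULT_COLUMNS]


def export_report(
    table: pd.DataFrame,
    out_dir,
    config: RunConfig | None = None,
    threshold: float = DEFAULT_POWER_THRESHOLD,
    heatmaps: bool = False,
) -> dict[str, Path]:
    """Write the results CSV, frontier CSV, config echo and optional heatmaps.

    Reruns with identical inputs produce byte-identical CSVs.  Returns the
    paths written, keyed by artifact name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    results_path = out / "results.csv"
    table[RESULT_COLUMNS].to_csv(results_path, index=False)
    paths["results"] = results_path

    frontier_path = out / "frontier.csv"
    frontier_frame(minimum_requirements(table, threshold)).to_csv(
        frontier_path, index=False
    )
    paths["frontier"] = frontier_path

    if config is not None:
        config_path = out / "run_config.yaml"
        config_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        paths["config"] = config_path

    if heatmaps and len(table):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        hm_dir = out / "heatmaps"
        hm_dir.mkdir(exist_ok=True)
        power = table[table["metric"] == "power"]
        keys = power[["shape", "model", "coefficient", "effect"]].drop_duplicates()
        for _, row in keys.iterrows():
            grid = heatmap_grid(
                table, row["shape"], row["model"], row["coefficient"],
                "power", row["effect"],
            )
            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.imshow(grid.values, origin="lower", cmap="viridis",
                           vmin=0, vmax=1, aspect="auto")
            ax.set_xticks(range(len(grid.columns)), grid.columns)
            ax.set_yticks(range(len(grid.index)), grid.index)
            ax.set_xlabel("time points")
            ax.set_ylabel("subjects per occasion")
            ax.set_title(
                f"power {row['coefficient']} | {row['shape']} / {row['model']} "
                f"/ e={row['effect']:g}"
            )
            fig.colorbar(im, ax=ax)
            name = (
                f"power_{row['shape']}_{row['model']}_"
                f"{row['coefficient'].replace('*', 'x').replace('^', '')}_"
                f"e{row['effect']:g}.png"
            )
            fig.savefig(hm_dir / name, dpi=120)
            plt.close(fig)
        paths["heatmaps"] = hm_dir

    logger.info("report written to %s", out)
    return paths
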