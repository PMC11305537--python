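"""Replicated simulation cells and the three performance criteria.

A *cell* pairs one data-generating scenario (shape, T, n, effect size) with
one fitted model and a replication count.  For each replication a fresh panel
is generated from its own deterministic seed and the model is fitted; the
cell then aggregates, per coefficient:

power
    share of replications with two-sided p < alpha (strict).
bias
    ``|mean(estimate) - true value|``; for a term the data-generating process
    does not contain, the true value is 0, so its "power" is a type-I error
    rate.
precision
    mean model-based standard error (the empirical SD of the estimates is
    kept alongside as a diagnostic).

The design matrix is identical across replications within a cell, so it is
factorized once and all responses are fitted in one batched solve; this is
exactly equivalent to refitting per replication.

Default model/data pairings follow the study's six-row catalog mixing right
fits, overfits (extra terms) and underfits (a second intervention present in
the data but not the model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import dgp
from .dgp import ScenarioSpec, replication_seed, true_coefficients
from .models import (
    DesignFactorization,
    ModelSpec,
    SingularDesignError,
    build_design,
    get_model,
    true_value_for_term,
)

__all__ = [
    "Pairing",
    "DEFAULT_PAIRINGS",
    "CellResult",
    "empirical_power",
    "bias",
    "precision",
    "run_cell",
    "run_grid",
    "RunConfig",
]

logger = logging.getLogger("itspower")

DEFAULT_ALPHA = 0.05
DEFAULT_REPS = 1000
#: a cell fails outright if more than this share of fits are singular
MAX_FAILURE_RATE = 0.01

RESULT_COLUMNS = [
    "scenario_id",
    "timepoints",
    "subjects",
    "effect",
    "shape",
    "model",
    "fit_quality",
    "coefficient",
    "metric",
    "value",
    "reps",
    "failures",
    "seed",
]


@dataclass(frozen=True)
class Pairing:
    """A (data shape, fitted model, fit-quality label) combination."""

    shape: str
    model: str
    fit_quality: str


#: The study's six pairings: the basic model as right fit, two overfits and an
#: underfit, the corrected two-intervention model, and the quadratic overfit.
DEFAULT_PAIRINGS = (
    Pairing("step_slope", "basic", "right_fit"),
    Pairing("step_only", "basic", "overfit"),
    Pairing("slope_only", "basic", "overfit"),
    Pairing("two_steps_slope", "basic", "underfit"),
    Pairing("two_steps_slope", "two_intervention_steps", "right_fit"),
    Pairing("step_slope", "quadratic", "overfit"),
)


def empirical_power(p_values: Sequence[float], alpha: float = DEFAULT_ALPHA) -> float:
    """Share of replications with p strictly below alpha."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(np.count_nonzero(p < alpha) / p.size)


def bias(estimates: Sequence[float], true_value: float) -> float:
    """Absolute difference between the mean estimate and the true value."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("estimates must be non-empty")
    return float(abs(est.mean() - true_value))


def precision(standard_errors: Sequence[float]) -> float:
    """Mean model-based standard error across replications."""
    se = np.asarray(standard_errors, dtype=float)
    if se.size == 0:
        raise ValueError("standard_errors must be non-empty")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    return float(se.mean())


@dataclass(frozen=True)
class CellResult:
    """Aggregated performance of one model on one scenario over replications."""

    scenario: ScenarioSpec
    shape: str
    model: str
    fit_quality: str
    reps: int
    failures: int
    base_seed: int
    alpha: float
    terms: tuple[str, ...]
    power: dict[str, float]
    bias: dict[str, float]
    precision: dict[str, float]
    mean_estimate: dict[str, float]
    empirical_sd: dict[str, float]
    true_values: dict[str, float]

    def metric(self, term: str, name: str) -> float:
        return getattr(self, name)[term]

    def to_rows(self, scenario_id: str | None = None) -> list[dict]:
        """Long-format rows, one per (coefficient, metric)."""
        s = self.scenario
        sid = scenario_id or scenario_key(s, self.shape)
        rows = []
        for term in self.terms:
            for metric in ("power", "bias", "precision", "mean_estimate", "empirical_sd"):
                rows.append(
                    {
                        "scenario_id": sid,
                        "timepoints": s.n_timepoints,
                        "subjects": s.n_subjects,
                        "effect": s.effect_size,
                        "shape": self.shape,
                        "model": self.model,
                        "fit_quality": self.fit_quality,
                        "coefficient": term,
                        "metric": metric,
                        "value": getattr(self, metric)[term],
                        "reps": self.reps,
                        "failures": self.failures,
                        "seed": self.base_seed,
                    }
                )
        return rows


def scenario_key(scenario: ScenarioSpec, shape: str) -> str:
    return (
        f"T{scenario.n_timepoints}_n{scenario.n_subjects}"
        f"_e{scenario.effect_size:g}_{shape}"
    )


def _simulate_responses(
    scenario: ScenarioSpec, reps: int, base_seed: int
) -> tuple[np.ndarray, int]:
    """Response matrix (n*T rows, reps columns), one panel per column."""
    n_records = scenario.n_subjects * scenario.n_timepoints
    responses = np.empty((n_records, reps))
    for r in range(reps):
        panel = dgp.generate_panel(
            scenario, seed=replication_seed(base_seed, scenario, r)
        )
        responses[:, r] = panel.score
    return responses, n_records


def run_cell(
    scenario: ScenarioSpec,
    shape: str | None = None,
    model: ModelSpec | str = "basic",
    reps: int = DEFAULT_REPS,
    base_seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    fit_quality: str = "unspecified",
) -> CellResult:
    """Run one simulation cell: generate ``reps`` panels, fit, aggregate.

    Deterministic in ``base_seed``: per-replication seeds depend only on
    (base_seed, scenario, shape, replication), never on the model, so
    different models fitted to the same cell see identical panels.
    Singular fits are skipped and counted; the cell errors out if more than
    1% of fits fail.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if isinstance(model, str):
        model = get_model(model)
    if shape is not None:
        scenario = scenario.with_shape(shape)
    shape = scenario.shape

    schedule = dgp.intervention_schedule(scenario.n_timepoints, shape)
    design_occ = build_design(schedule, model)
    design = np.repeat(design_occ, scenario.n_subjects, axis=0)
    fact = DesignFactorization(design, terms=model.terms)

    responses, _ = _simulate_responses(scenario, reps, base_seed)
    batch = fact.fit(responses)

    # Singularity cannot arise once the shared design factorizes, but guard
    # against non-finite per-replication output (e.g. zero-variance responses
    # give zero SEs and infinite t values, which are legitimate; NaNs are not).
    ok = np.all(np.isfinite(batch.estimates), axis=0) & np.all(
        np.isfinite(batch.p_values), axis=0
    )
    failures = int(reps - ok.sum())
    if failures > MAX_FAILURE_RATE * reps:
        raise RuntimeError(
            f"{failures}/{reps} fits failed in cell "
            f"{scenario_key(scenario, shape)} with model {model.name}"
        )

    params = true_coefficients(scenario)
    power_d, bias_d, prec_d, mean_d, sd_d, true_d = {}, {}, {}, {}, {}, {}
    for i, term in enumerate(model.terms):
        est = batch.estimates[i, ok]
        se = batch.standard_errors[i, ok]
        pv = batch.p_values[i, ok]
        tv = true_value_for_term(term, params)
        power_d[term] = empirical_power(pv, alpha)
        bias_d[term] = bias(est, tv)
        prec_d[term] = float(se.mean())
        mean_d[term] = float(est.mean())
        sd_d[term] = float(est.std(ddof=1)) if est.size > 1 else 0.0
        true_d[term] = tv

    return CellResult(
        scenario=scenario,
        shape=shape,
        model=model.name,
        fit_quality=fit_quality,
        reps=int(ok.sum()),
        failures=failures,
        base_seed=base_seed,
        alpha=alpha,
        terms=model.terms,
        power=power_d,
        bias=bias_d,
        precision=prec_d,
        mean_estimate=mean_d,
        empirical_sd=sd_d,
        true_values=true_d,
    )


def run_cell_naive(
    scenario: ScenarioSpec,
    shape: str | None = None,
    model: ModelSpec | str = "basic",
    reps: int = DEFAULT_REPS,
    base_seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    fit_quality: str = "unspecified",
) -> CellResult:
    """Reference path: refit the design per replication (for equivalence tests)."""
    if isinstance(model, str):
        model = get_model(model)
    if shape is not None:
        scenario = scenario.with_shape(shape)
    estimates, ses, pvals = [], [], []
    failures = 0
    for r in range(reps):
        panel = dgp.generate_panel(
            scenario, seed=replication_seed(base_seed, scenario, r)
        )
        design = build_design(panel, model)
        try:
            fit = DesignFactorization(design, terms=model.terms).fit(panel.score)
        except SingularDesignError:
            failures += 1
            continue
        estimates.append(fit.estimates)
        ses.append(fit.standard_errors)
        pvals.append(fit.p_values)
    if failures > MAX_FAILURE_RATE * reps:
        raise RuntimeError(f"{failures}/{reps} fits failed")
    est = np.array(estimates).T
    se = np.array(ses).T
    pv = np.array(pvals).T
    params = true_coefficients(scenario)
    power_d, bias_d, prec_d, mean_d, sd_d, true_d = {}, {}, {}, {}, {}, {}
    for i, term in enumerate(model.terms):
        tv = true_value_for_term(term, params)
        power_d[term] = empirical_power(pv[i], alpha)
        bias_d[term] = bias(est[i], tv)
        prec_d[term] = float(se[i].mean())
        mean_d[term] = float(est[i].mean())
        sd_d[term] = float(est[i].std(ddof=1)) if est.shape[1] > 1 else 0.0
        true_d[term] = tv
    return CellResult(
        scenario=scenario,
        shape=scenario.shape,
        model=model.name,
        fit_quality=fit_quality,
        reps=reps - failures,
        failures=failures,
        base_seed=base_seed,
        alpha=alpha,
        terms=model.terms,
        power=power_d,
        bias=bias_d,
        precision=prec_d,
        mean_estimate=mean_d,
        empirical_sd=sd_d,
        true_values=true_d,
    )


@dataclass
class RunConfig:
    """Configuration for a full grid run (serializable to YAML/JSON)."""

    timepoints: tuple[int, ...] = dgp.DEFAULT_TIMEPOINTS
    subjects: tuple[int, ...] = dgp.DEFAULT_SUBJECTS
    effects: tuple[float, ...] = dgp.DEFAULT_EFFECTS
    shapes: tuple[str, ...] | None = None  # None -> pairing catalog drives shapes
    sampling_mode: str = "cross_sectional"
    reps: int = DEFAULT_REPS
    base_seed: int = 0
    alpha: float = DEFAULT_ALPHA

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("timepoints", "subjects", "effects", "shapes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "timepoints": list(self.timepoints),
            "subjects": list(self.subjects),
            "effects": list(self.effects),
            "shapes": list(self.shapes) if self.shapes else None,
            "sampling_mode": self.sampling_mode,
            "reps": self.reps,
            "base_seed": self.base_seed,
            "alpha": self.alpha,
        }

    def pairings(self) -> tuple[Pairing, ...]:
        if self.shapes is None:
            return DEFAULT_PAIRINGS
        return tuple(p for p in DEFAULT_PAIRINGS if p.shape in self.shapes)


def run_grid(
    config: RunConfig,
    pairings: Sequence[Pairing] | None = None,
    existing: pd.DataFrame | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every (scenario x pairing) cell and return the long-format table.

    Cells whose (scenario_id, model) pair already appears in ``existing`` are
    skipped, so an interrupted run can be resumed from its partial output.
    Row order is deterministic: pairings in catalog order, scenarios in grid
    order, coefficients in term order, metrics in fixed order.
    """
    pairings = tuple(pairings) if pairings is not None else config.pairings()
    scenarios = dgp.build_scenario_grid(
        config.timepoints,
        config.subjects,
        config.effects,
        sampling_mode=config.sampling_mode,
    )
    done: set[tuple[str, str]] = set()
    frames: list[pd.DataFrame] = []
    if existing is not None and len(existing):
        done = set(zip(existing["scenario_id"], existing["model"]))
        frames.append(existing)

    rows: list[dict] = []
    for pairing in pairings:
        for scenario in scenarios:
            sid = scenario_key(scenario.with_shape(pairing.shape), pairing.shape)
            if (sid, pairing.model) in done:
                continue
            cell = run_cell(
                scenario,
                shape=pairing.shape,
                model=pairing.model,
                reps=config.reps,
                base_seed=config.base_seed,
                alpha=config.alpha,
                fit_quality=pairing.fit_quality,
            )
            rows.extend(cell.to_rows(sid))
            if progress:
                logger.info(
                    "cell done scenario=%s model=%s seed=%d failures=%d",
                    sid,
                    pairing.model,
                    config.base_seed,
                    cell.failures,
                )
    frames.append(pd.DataFrame(rows, columns=RESULT_COLUMNS))
    out = pd.concat(frames, ignore_index=True)
    return out[RESULT_COLUMNS]
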