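"""Data-generating process for the interrupted time series simulation study.

The generator emulates cohorts of standardised test scores measured at ``T``
equally spaced occasions.  Each score is a deterministic growth line —
baseline level plus a constant gain of :data:`DEFAULT_SLOPE` points per
occasion — perturbed by a baseline draw and occasion-level noise, with an
intervention interrupting the line at the series midpoint.  Intervention
effects are expressed as a fraction of the pre-intervention slope and applied
as negative shocks (the motivating setting is learning loss).

Four intervention shapes are supported: an immediate level shift only
(``step_only``), a change of trend only (``slope_only``), both
(``step_slope``), and both plus a second, smaller level shift at 75% of the
series (``two_steps_slope``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SHAPES",
    "SAMPLING_MODES",
    "DEFAULT_TIMEPOINTS",
    "DEFAULT_SUBJECTS",
    "DEFAULT_EFFECTS",
    "ScenarioSpec",
    "InterventionSchedule",
    "TrueParams",
    "SimulatedPanel",
    "build_scenario_grid",
    "intervention_schedule",
    "true_coefficients",
    "mean_function",
    "generate_panel",
    "replication_seed",
]

SHAPES = ("step_only", "slope_only", "step_slope", "two_steps_slope")
SAMPLING_MODES = ("cross_sectional", "longitudinal")

#: Study-default grid: 8 series lengths x 8 cohort sizes x 6 effect sizes = 384 scenarios.
DEFAULT_TIMEPOINTS = (6, 8, 10, 12, 14, 16, 18, 20)
DEFAULT_SUBJECTS = (100, 300, 500, 700, 900, 1100, 1300, 1500)
DEFAULT_EFFECTS = (0.01, 0.025, 0.05, 0.10, 0.15, 0.30)

DEFAULT_BASELINE_MEAN = 170.0
DEFAULT_BASELINE_VAR = 25.0
DEFAULT_SLOPE = 16.5
DEFAULT_NOISE_VAR = 25.0
DEFAULT_SECOND_STEP_FRACTION = 0.5


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation grid.

    Parameters
    ----------
    n_timepoints
        Number of measurement occasions ``T``; must be even and >= 6 so the
        intervention can sit exactly between the two middle occasions.
    n_subjects
        Scores generated per occasion.
    effect_size
        Intervention magnitude as a fraction of the pre-intervention slope;
        applied with negative sign, so a positive value is a shock that slows
        growth (negative values flip every intervention coefficient's sign).
    shape
        Which intervention terms are present in the generative mean.
    sampling_mode
        ``cross_sectional`` draws a fresh baseline deviation for every record;
        ``longitudinal`` draws one baseline deviation per subject, shared
        across that subject's occasions.
    """

    n_timepoints: int
    n_subjects: int
    effect_size: float
    shape: str = "step_slope"
    sampling_mode: str = "cross_sectional"
    baseline_mean: float = DEFAULT_BASELINE_MEAN
    baseline_var: float = DEFAULT_BASELINE_VAR
    slope: float = DEFAULT_SLOPE
    noise_var: float = DEFAULT_NOISE_VAR
    second_step_fraction: float = DEFAULT_SECOND_STEP_FRACTION

    def __post_init__(self) -> None:
        if self.n_timepoints < 6 or self.n_timepoints % 2:
            raise ValueError(
                f"n_timepoints must be even and >= 6, got {self.n_timepoints}"
            )
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        if self.sampling_mode not in SAMPLING_MODES:
            raise ValueError(
                f"unknown sampling_mode {self.sampling_mode!r}; "
                f"expected one of {SAMPLING_MODES}"
            )
        if self.baseline_var < 0 or self.noise_var < 0:
            raise ValueError("variances must be non-negative")

    def with_shape(self, shape: str) -> "ScenarioSpec":
        return replace(self, shape=shape)


@dataclass(frozen=True)
class InterventionSchedule:
    """Centered time axis and post-intervention indicators for a series.

    Occasions are indexed 1..T; centering subtracts ``T/2 + 0.5`` so the
    first intervention falls at centered time 0, exactly between the two
    middle occasions, and the centered times are half-integers symmetric
    about zero.
    """

    n_timepoints: int
    raw_times: np.ndarray
    centered_times: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    second_boundary_index: int | None = None

    def __post_init__(self) -> None:
        for name in ("raw_times", "centered_times", "x1", "x2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))

    @property
    def has_second_intervention(self) -> bool:
        return self.second_boundary_index is not None


@dataclass(frozen=True)
class TrueParams:
    """Generative coefficient vector implied by a scenario.

    ``beta_t2`` is always zero: a quadratic trend exists only in fitted
    (overfit) models, never in the data.
    """

    beta0: float
    beta1: float
    beta_step: float = 0.0
    beta_slopechange: float = 0.0
    beta_step2: float = 0.0
    beta_t2: float = 0.0


@dataclass(frozen=True)
class SimulatedPanel:
    """A simulated score panel in long (record) form.

    Arrays are aligned: record ``i`` is subject ``subject_id[i]`` observed at
    occasion ``occasion[i]`` (1-based) with score ``score[i]``.  Records are
    ordered by occasion, then subject.
    """

    scenario: ScenarioSpec
    schedule: InterventionSchedule
    subject_id: np.ndarray
    occasion: np.ndarray
    centered_time: np.ndarray
    score: np.ndarray
    seed: object = None

    def __len__(self) -> int:
        return len(self.score)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "occasion": self.occasion,
                "centered_time": self.centered_time,
                "score": self.score,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_scenario_grid(
    timepoint_values: Sequence[int] = DEFAULT_TIMEPOINTS,
    subject_values: Sequence[int] = DEFAULT_SUBJECTS,
    effect_values: Sequence[float] = DEFAULT_EFFECTS,
    **scenario_kwargs,
) -> list[ScenarioSpec]:
    """Cartesian product of the grid axes, in lexicographic order.

    Order is (timepoints, subjects, effect size), each axis sorted as given.
    The study defaults produce 8 * 8 * 6 = 384 scenarios.
    """
    for name, values in (
        ("timepoint_values", timepoint_values),
        ("subject_values", subject_values),
        ("effect_values", effect_values),
    ):
        if not len(values):
            raise ValueError(f"{name} must be non-empty")
        if any(v <= 0 for v in values):
            raise ValueError(f"{name} must be positive")
    return [
        ScenarioSpec(n_timepoints=t, n_subjects=n, effect_size=e, **scenario_kwargs)
        for t, n, e in itertools.product(timepoint_values, subject_values, effect_values)
    ]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def intervention_schedule(n_timepoints: int, shape: str = "step_slope") -> InterventionSchedule:
    """Build the centered time axis and indicator vectors for one series.

    The first intervention sits between occasions T/2 and T/2 + 1 (centered
    time 0).  For ``two_steps_slope`` the second boundary follows occasion
    ``k = round-half-up(0.75 T)``, so ``x2`` flags the last ``T - k``
    occasions.
    """
    if n_timepoints < 6 or n_timepoints % 2:
        raise ValueError(f"n_timepoints must be even and >= 6, got {n_timepoints}")
    if shape not in SHAPES:
        raise ValueError(f"unknown shape {shape!r}")
    raw = np.arange(1, n_timepoints + 1)
    centered = raw - (n_timepoints / 2 + 0.5)
    x1 = (centered > 0).astype(np.int64)
    second_boundary = None
    x2 = np.zeros(n_timepoints, dtype=np.int64)
    if shape == "two_steps_slope":
        second_boundary = _round_half_up(0.75 * n_timepoints)
        if second_boundary >= n_timepoints:
            raise ValueError(
                f"second intervention boundary k={second_boundary} leaves no "
                f"occasion after it (T={n_timepoints})"
            )
        x2 = (raw > second_boundary).astype(np.int64)
    return InterventionSchedule(
        n_timepoints=n_timepoints,
        raw_times=raw,
        centered_times=centered,
        x1=x1,
        x2=x2,
        second_boundary_index=second_boundary,
    )


def true_coefficients(scenario: ScenarioSpec) -> TrueParams:
    """Generative coefficients for a scenario.

    ``beta0`` is the noiseless mean extrapolated to centered time 0:
    ``baseline_mean + slope * (T/2 - 0.5)``.  Step and slope-change effects
    equal ``-effect_size * slope`` for the shapes that include them, and the
    second step is ``second_step_fraction`` of the first.
    """
    t = scenario.n_timepoints
    beta0 = scenario.baseline_mean + scenario.slope * (t / 2 - 0.5)
    shock = -scenario.effect_size * scenario.slope
    has_step = scenario.shape in ("step_only", "step_slope", "two_steps_slope")
    has_slope = scenario.shape in ("slope_only", "step_slope", "two_steps_slope")
    beta_step = shock if has_step else 0.0
    beta_slopechange = shock if has_slope else 0.0
    beta_step2 = (
        scenario.second_step_fraction * beta_step
        if scenario.shape == "two_steps_slope"
        else 0.0
    )
    return TrueParams(
        beta0=beta0,
        beta1=scenario.slope,
        beta_step=beta_step,
        beta_slopechange=beta_slopechange,
        beta_step2=beta_step2,
    )


def mean_function(centered_time, x1, x2, true_params: TrueParams):
    """Expected score at a centered time given the intervention indicators.

    ``beta0 + beta1 t + x1 (beta_step + beta_slopechange t) + x2 beta_step2``.
    Pre-intervention (x1 = x2 = 0) this is the uninterrupted growth line.
    """
    t = np.asarray(centered_time, dtype=float)
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    p = true_params
    return (
        p.beta0
        + p.beta1 * t
        + x1 * (p.beta_step + p.beta_slopechange * t)
        + x2 * p.beta_step2
    )


def occasion_means(scenario: ScenarioSpec) -> np.ndarray:
    """Noiseless expected score at each of the scenario's occasions."""
    sched = intervention_schedule(scenario.n_timepoints, scenario.shape)
    return mean_function(
        sched.centered_times, sched.x1, sched.x2, true_coefficients(scenario)
    )


def replication_seed(
    base_seed: int, scenario: ScenarioSpec, replication: int
) -> np.random.SeedSequence:
    """Deterministic seed for one (scenario, shape, replication) triple.

    The fitted model is deliberately absent from the key: all models fitted to
    the same scenario/shape/replication see the identical panel, which makes
    model comparisons paired (common random numbers).
    """
    effect_key = abs(int(round(scenario.effect_size * 10_000)))
    sign_key = 1 if scenario.effect_size < 0 else 0
    mode_key = SAMPLING_MODES.index(scenario.sampling_mode)
    return np.random.SeedSequence(
        [
            int(base_seed),
            scenario.n_timepoints,
            scenario.n_subjects,
            effect_key,
            sign_key,
            SHAPES.index(scenario.shape),
            mode_key,
            int(replication),
        ]
    )


def generate_panel(
    scenario: ScenarioSpec,
    shape: str | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> SimulatedPanel:
    """Simulate one score panel.

    Every record's score is the generative mean at its occasion plus a
    baseline deviation ``b ~ N(0, baseline_var)`` plus occasion noise
    ``e ~ N(0, noise_var)``.  In ``cross_sectional`` mode ``b`` is drawn
    independently per record; in ``longitudinal`` mode once per subject.
    Identical seeds produce bit-identical panels.
    """
    if shape is not None and shape != scenario.shape:
        scenario = scenario.with_shape(shape)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t, n = scenario.n_timepoints, scenario.n_subjects
    means = occasion_means(scenario)
    sched = intervention_schedule(t, scenario.shape)

    # occasion-major layout: occasion 1's n records first, then occasion 2's, ...
    occ = np.repeat(sched.raw_times, n)
    ctime = np.repeat(sched.centered_times, n)
    subj = np.tile(np.arange(1, n + 1), t)
    mu = np.repeat(means, n)

    if scenario.sampling_mode == "longitudinal":
        b_subject = rng.normal(0.0, math.sqrt(scenario.baseline_var), size=n)
        b = np.tile(b_subject, t)
    else:
        b = rng.normal(0.0, math.sqrt(scenario.baseline_var), size=n * t)
    eps = rng.normal(0.0, math.sqrt(scenario.noise_var), size=n * t)
    score = mu + b + eps

    return SimulatedPanel(
        scenario=scenario,
        schedule=sched,
        subject_id=subj,
        occasion=occ,
        centered_time=ctime,
        score=score,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )
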