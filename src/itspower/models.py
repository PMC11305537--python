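"""Segmented-regression model variants and the OLS fitting engine.

Each model is an ordered list of design terms built from the centered time
axis ``T`` and the post-intervention indicators ``X1`` (first intervention)
and ``X2`` (second).  The catalog covers the variants the simulation study
pairs with its data shapes:

``basic``
    intercept + T + X1 + T*X1 — level and trend change at one intervention.
``two_intervention_steps``
    adds an X2 step dummy with a single shared post-intervention slope term.
``two_intervention_full``
    adds both X2 and T*X2 (a separate post-second-intervention slope).
``quadratic``
    basic plus a T^2 trend term.
``combined``
    the full specification: both interventions plus the quadratic trend.

Coefficients are estimated by ordinary least squares with classical
(homoskedastic) standard errors and two-sided t-tests.  Because the Monte
Carlo loop refits the same design matrix to thousands of response vectors,
the solver is factorized: :class:`DesignFactorization` performs the
decomposition once and fits any number of responses in a single batched
solve, with results identical to a one-at-a-time refit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .dgp import InterventionSchedule, SimulatedPanel, TrueParams

__all__ = [
    "TERMS",
    "ModelSpec",
    "FitResult",
    "SingularDesignError",
    "model_catalog",
    "get_model",
    "build_design",
    "fit_ols",
    "DesignFactorization",
    "true_value_for_term",
]

#: Recognised design terms, in canonical order.
TERMS = ("intercept", "T", "X1", "T*X1", "X2", "T*X2", "T^2")

# condition threshold for declaring a design rank-deficient
_RCOND = 1e-10


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the design matrix is (numerically) rank-deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """A named segmented-regression variant: an ordered tuple of terms."""

    name: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [t for t in self.terms if t not in TERMS]
        if unknown:
            raise ValueError(f"unknown design terms {unknown}; allowed: {TERMS}")
        if "intercept" not in self.terms:
            raise ValueError("every model must include an intercept")
        if "T*X1" in self.terms and "X1" not in self.terms:
            raise ValueError("T*X1 requires X1")

    @property
    def needs_x2(self) -> bool:
        return "X2" in self.terms or "T*X2" in self.terms

    def __len__(self) -> int:
        return len(self.terms)


_CATALOG = (
    ModelSpec("basic", ("intercept", "T", "X1", "T*X1")),
    ModelSpec("two_intervention_steps", ("intercept", "T", "X1", "X2", "T*X1")),
    ModelSpec("two_intervention_full", ("intercept", "T", "X1", "T*X1", "X2", "T*X2")),
    ModelSpec("quadratic", ("intercept", "T", "X1", "T*X1", "T^2")),
    ModelSpec("combined", ("intercept", "T", "X1", "T*X1", "X2", "T*X2", "T^2")),
)


def model_catalog() -> list[ModelSpec]:
    """The five distinct model variants, in stable order."""
    return list(_CATALOG)


def get_model(name: str) -> ModelSpec:
    for spec in _CATALOG:
        if spec.name == name:
            return spec
    raise KeyError(
        f"unknown model {name!r}; available: {[s.name for s in _CATALOG]}"
    )


@dataclass(frozen=True)
class FitResult:
    """OLS estimates with classical inference for one fitted model.

    Arrays are aligned with ``terms``.  ``second_step_total_contrast`` is the
    total level since the second intervention read against the first step
    (estimate of X1 term + X2 term minus X1 term ... i.e. the X2 coefficient
    restated as "total minus first step" is exposed where both dummies are
    present; see :meth:`from_arrays`).
    """

    terms: tuple[str, ...]
    estimates: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    residual_variance: float
    dof: int
    n_obs: int

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.terms.index(term)
        return {
            "estimate": float(self.estimates[i]),
            "se": float(self.standard_errors[i]),
            "t": float(self.t_values[i]),
            "p": float(self.p_values[i]),
        }

    @property
    def second_step_total_contrast(self) -> float | None:
        """Total step since the second intervention: X1 + X2 coefficients.

        With an additive X2 dummy the X2 coefficient is the *incremental*
        second step; the total post-second-intervention level change (the
        quantity sometimes read off as "beta4", with the incremental step
        recovered as beta4 - beta2) is the sum of the two step coefficients.
        """
        if "X1" not in self.terms or "X2" not in self.terms:
            return None
        return float(
            self.estimates[self.terms.index("X1")]
            + self.estimates[self.terms.index("X2")]
        )

    def to_dict(self) -> dict:
        out = {
            term: self[term] for term in self.terms
        }
        out["residual_variance"] = self.residual_variance
        out["dof"] = self.dof
        out["n_obs"] = self.n_obs
        if self.second_step_total_contrast is not None:
            out["second_step_total_contrast"] = self.second_step_total_contrast
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _term_column(term, ctime, x1, x2):
    ctime = np.asarray(ctime, dtype=float)
    if term == "intercept":
        return np.ones_like(ctime)
    if term == "T":
        return ctime
    if term == "X1":
        return np.asarray(x1, dtype=float)
    if term == "T*X1":
        return ctime * np.asarray(x1, dtype=float)
    if term == "X2":
        return np.asarray(x2, dtype=float)
    if term == "T*X2":
        return ctime * np.asarray(x2, dtype=float)
    if term == "T^2":
        return ctime**2
    raise ValueError(f"unknown term {term!r}")


def build_design(source, model: ModelSpec | str) -> np.ndarray:
    """Design matrix (one row per record/occasion, columns in term order).

    ``source`` is a :class:`~itspower.dgp.SimulatedPanel` (one row per
    record) or an :class:`~itspower.dgp.InterventionSchedule` (one row per
    occasion).  Models containing X2 terms require a schedule with a second
    intervention boundary.
    """
    if isinstance(model, str):
        model = get_model(model)
    if isinstance(source, SimulatedPanel):
        sched = source.schedule
        ctime = source.centered_time
        occ = source.occasion
        x1 = sched.x1[occ - 1]
        x2 = sched.x2[occ - 1]
    elif isinstance(source, InterventionSchedule):
        sched = source
        ctime, x1, x2 = sched.centered_times, sched.x1, sched.x2
    else:
        raise TypeError(f"cannot build a design from {type(source).__name__}")
    if model.needs_x2 and not sched.has_second_intervention:
        raise ValueError(
            f"model {model.name!r} needs an X2 indicator but the schedule has "
            "no second intervention boundary"
        )
    return np.column_stack([_term_column(t, ctime, x1, x2) for t in model.terms])


class DesignFactorization:
    """One-time decomposition of a design matrix for batched OLS fits.

    Solves the least-squares problem via the economy QR factorization
    ``X = QR``; coefficient covariance is ``sigma^2 (R'R)^{-1}``.  Raises
    :class:`SingularDesignError` (naming the collinear columns) if the design
    is numerically rank-deficient.
    """

    def __init__(self, design: np.ndarray, terms: Sequence[str] | None = None):
        design = np.asarray(design, dtype=float)
        if design.ndim != 2:
            raise ValueError("design must be 2-D")
        n, p = design.shape
        if n <= p:
            raise ValueError(f"need more observations ({n}) than terms ({p})")
        self.terms = tuple(terms) if terms is not None else tuple(
            f"x{i}" for i in range(p)
        )
        self.design = design
        self.n_obs, self.n_terms = n, p
        self.dof = n - p
        q, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        if diag.min() <= _RCOND * max(diag.max(), 1.0):
            bad = [self.terms[i] for i in np.nonzero(
                diag <= _RCOND * max(diag.max(), 1.0))[0]]
            raise SingularDesignError(
                f"design matrix is rank-deficient; collinear terms: {bad}"
            )
        self._q, self._r = q, r
        rinv = np.linalg.solve(r, np.eye(p))
        self._xtx_inv_diag = np.sum(rinv**2, axis=1)

    def coefficients(self, responses: np.ndarray) -> np.ndarray:
        """Least-squares coefficients; batched over trailing response columns."""
        y = np.asarray(responses, dtype=float)
        return np.linalg.solve(self._r, self._q.T @ y)

    def fit(self, responses: np.ndarray) -> "BatchFitResult | FitResult":
        """Fit one response vector (-> FitResult) or a (n_obs, reps) batch."""
        y = np.asarray(responses, dtype=float)
        single = y.ndim == 1
        if single:
            y = y[:, None]
        if y.shape[0] != self.n_obs:
            raise ValueError(
                f"responses have {y.shape[0]} rows; design has {self.n_obs}"
            )
        beta = self.coefficients(y)
        resid = y - self.design @ beta
        rss = np.einsum("ij,ij->j", resid, resid)
        sigma2 = rss / self.dof
        se = np.sqrt(np.outer(self._xtx_inv_diag, sigma2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pval = 2.0 * stats.t.sf(np.abs(tval), df=self.dof)
        batch = BatchFitResult(
            terms=self.terms,
            estimates=beta,
            standard_errors=se,
            t_values=tval,
            p_values=pval,
            residual_variance=sigma2,
            dof=self.dof,
            n_obs=self.n_obs,
        )
        return batch.single(0) if single else batch


@dataclass(frozen=True)
class BatchFitResult:
    """OLS results for many response vectors sharing one design.

    Coefficient arrays have shape (n_terms, n_replications).
    """

    terms: tuple[str, ...]
    estimates: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    residual_variance: np.ndarray
    dof: int
    n_obs: int

    @property
    def n_fits(self) -> int:
        return self.estimates.shape[1]

    def single(self, j: int) -> FitResult:
        return FitResult(
            terms=self.terms,
            estimates=self.estimates[:, j].copy(),
            standard_errors=self.standard_errors[:, j].copy(),
            t_values=self.t_values[:, j].copy(),
            p_values=self.p_values[:, j].copy(),
            residual_variance=float(self.residual_variance[j]),
            dof=self.dof,
            n_obs=self.n_obs,
        )


def fit_ols(
    design: np.ndarray,
    responses: np.ndarray,
    terms: Sequence[str] | None = None,
) -> FitResult:
    """OLS fit of one response vector with classical t-based inference."""
    result = DesignFactorization(design, terms=terms).fit(np.asarray(responses))
    assert isinstance(result, FitResult)
    return result


def fit_panel(panel: SimulatedPanel, model: ModelSpec | str) -> FitResult:
    """Convenience: build the design for a panel and fit it."""
    if isinstance(model, str):
        model = get_model(model)
    design = build_design(panel, model)
    return fit_ols(design, panel.score, terms=model.terms)


def true_value_for_term(term: str, params: TrueParams) -> float:
    """Generative value of a design term's coefficient (0 if absent from the DGP)."""
    return {
        "intercept": params.beta0,
        "T": params.beta1,
        "X1": params.beta_step,
        "T*X1": params.beta_slopechange,
        "X2": params.beta_step2,
        "T*X2": 0.0,
        "T^2": params.beta_t2,
    }[term]
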