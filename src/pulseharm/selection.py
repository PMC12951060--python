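"""Logistic model fitting and AIC-guided variable selection.

Sex-stratified logistic regressions predict severe coronary lesions
(SYNTAX score >= 22) from inter-hand harmonic difference features.  Three
greedy searches — forward selection, backward elimination, and bidirectional
stepwise — minimize AIC = 2k - 2*log-likelihood (k counts the intercept);
the winner across searches is the model with the smallest AIC, ties broken
toward fewer parameters and then lexicographically.

Fitting is maximum likelihood via Newton iterations (statsmodels ``Logit``,
gradient tolerance 1e-8, at most 100 iterations) with an always-estimated
intercept; complete separation and singular designs raise explicit errors
instead of returning silently diverged coefficients.  Reported per-variable
statistics are Wald: SE, t statistic (coefficient/SE) and its normal-theory
two-sided P value, matching the coefficient-table convention of clinical
logistic reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from pulseharm.errors import SeparationError, SingularDesignError

logger = logging.getLogger(__name__)

_AIC_EPS = 1e-10  # a move must beat this margin to count as an AIC decrease


@dataclass
class FittedModel:
    """A converged logistic fit with its Wald coefficient table."""

    variables: list[str]
    coefficients: pd.Series  # indexed by "(intercept)" + variables
    standard_errors: pd.Series
    t_statistics: pd.Series
    p_values: pd.Series
    log_likelihood: float
    aic: float
    n_obs: int
    n_events: int
    converged: bool = True

    @property
    def k(self) -> int:
        """Number of estimated parameters including the intercept."""
        return len(self.variables) + 1

    def check_aic_consistency(self, tol: float = 1e-8) -> None:
        expected = 2.0 * self.k - 2.0 * self.log_likelihood
        if abs(expected - self.aic) > tol:
            raise AssertionError(
                f"AIC {self.aic} inconsistent with 2k - 2l = {expected}"
            )

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Predicted event probabilities for a feature table."""
        from scipy.special import expit

        eta = np.full(len(features), self.coefficients["(intercept)"])
        for v in self.variables:
            eta = eta + self.coefficients[v] * features[v].to_numpy(dtype=float)
        return expit(eta)

    def coefficient_table(self) -> pd.DataFrame:
        """Per-variable table with columns Coefficient / SE / tStat / P Value."""
        return pd.DataFrame(
            {
                "Coefficient": self.coefficients,
                "SE": self.standard_errors,
                "tStat": self.t_statistics,
                "P Value": self.p_values,
            }
        )

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "standard_errors": {k: float(v) for k, v in self.standard_errors.items()},
            "t_statistics": {k: float(v) for k, v in self.t_statistics.items()},
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "log_likelihood": float(self.log_likelihood),
            "aic": float(self.aic),
            "n_obs": int(self.n_obs),
            "n_events": int(self.n_events),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FittedModel":
        idx = ["(intercept)"] + list(payload["variables"])
        return cls(
            variables=list(payload["variables"]),
            coefficients=pd.Series(payload["coefficients"]).reindex(idx),
            standard_errors=pd.Series(payload["standard_errors"]).reindex(idx),
            t_statistics=pd.Series(payload["t_statistics"]).reindex(idx),
            p_values=pd.Series(payload["p_values"]).reindex(idx),
            log_likelihood=payload["log_likelihood"],
            aic=payload["aic"],
            n_obs=payload["n_obs"],
            n_events=payload["n_events"],
        )


@dataclass
class SelectionResult:
    """Outcome of one greedy search."""

    method: str
    selected: list[str]
    model: FittedModel
    aic_trajectory: list[float]
    warnings: list[str] = field(default_factory=list)


def _design(features: pd.DataFrame, variables: list[str]) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(features))]
        + [features[v].to_numpy(dtype=float) for v in variables]
    )
    return X


def _check_rank(X: np.ndarray, variables: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that do not increase the rank incrementally
        collinear = []
        kept = X[:, :1]
        for j, name in enumerate(variables, start=1):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                collinear.append(name)
            else:
                kept = cand
        raise SingularDesignError(collinear or list(variables))


def fit_logistic(features: pd.DataFrame, labels: np.ndarray | pd.Series,
                 variables: list[str] | None = None) -> FittedModel:
    """Maximum-likelihood logistic fit of ``labels`` on ``variables``.

    Raises
    ------
    SeparationError
        Complete separation (the likelihood has no finite maximizer).
    SingularDesignError
        Rank-deficient design; names the collinear columns.
    ValueError
        Missing values, or only one outcome class present.
    """
    if variables is None:
        variables = [c for c in features.columns]
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise ValueError("need at least one event and one non-event")
    X = _design(features, variables)
    if np.any(~np.isfinite(X)):
        raise ValueError("features contain missing or non-finite values")
    _check_rank(X, variables)

    try:
        with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore"):
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0,
                warn_convergence=False,
            )
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"complete separation: {exc}") from exc
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"Hessian singular during Newton fit: {exc}") from exc
    probs = res.predict(X)
    if np.all(np.abs(probs - y) < 1e-6) or res.llf > -1e-3:
        raise SeparationError("complete separation: fitted probabilities reached 0/1")
    idx = ["(intercept)"] + list(variables)
    return FittedModel(
        variables=list(variables),
        coefficients=pd.Series(np.asarray(res.params), index=idx),
        standard_errors=pd.Series(np.asarray(res.bse), index=idx),
        t_statistics=pd.Series(np.asarray(res.tvalues), index=idx),
        p_values=pd.Series(np.asarray(res.pvalues), index=idx),
        log_likelihood=float(res.llf),
        aic=float(2 * (len(variables) + 1) - 2 * res.llf),
        n_obs=len(y),
        n_events=n_events,
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def aic_of(model: FittedModel) -> float:
    """AIC = 2k - 2*log-likelihood; verifies internal consistency first."""
    model.check_aic_consistency()
    return model.aic


def drop_degenerate(features: pd.DataFrame, candidates: list[str]) -> list[str]:
    """Remove zero-variance candidates (e.g. C0/P0-derived columns)."""
    kept, dropped = [], []
    for c in candidates:
        col = features[c].to_numpy(dtype=float)
        if np.ptp(col) <= 1e-12 * max(1.0, np.max(np.abs(col), initial=0.0)):
            dropped.append(c)
        else:
            kept.append(c)
    if dropped:
        logger.info("dropped %d zero-variance candidates: %s", len(dropped), dropped)
    return kept


def _try_fit(features, labels, variables) -> FittedModel | None:
    try:
        return fit_logistic(features, labels, variables)
    except (SeparationError, SingularDesignError):
        return None


def _best_move(features, labels, current: list[str], moves: list[tuple[str, list[str]]]):
    """Lowest-AIC candidate among the proposed variable sets.

    Ties within 1e-10 are broken lexicographically on the moved variable name.
    """
    best = None
    for name, variables in sorted(moves):
        fit = _try_fit(features, labels, variables)
        if fit is None:
            continue
        if best is None or fit.aic < best[2].aic - _AIC_EPS:
            best = (name, variables, fit)
    return best


def forward_select(features: pd.DataFrame, labels, candidates: list[str]) -> SelectionResult:
    """Start from the intercept-only model, greedily add while AIC decreases."""
    candidates = drop_degenerate(features, candidates)
    current: list[str] = []
    model = fit_logistic(features, labels, current)
    trajectory = [model.aic]
    notes: list[str] = []
    remaining = sorted(candidates)
    while remaining:
        move = _best_move(features, labels, current,
                          [(v, current + [v]) for v in remaining])
        if move is None or move[2].aic >= model.aic - _AIC_EPS:
            break
        current, model = move[1], move[2]
        remaining.remove(move[0])
        trajectory.append(model.aic)
    return SelectionResult("forward", current, model, trajectory, notes)


def backward_eliminate(features: pd.DataFrame, labels, candidates: list[str]) -> SelectionResult:
    """Start from the full model, greedily remove while AIC decreases.

    Falls back to forward selection (with a recorded warning) when the full
    model cannot be fitted — separation, singularity, or more parameters than
    observations.
    """
    candidates = drop_degenerate(features, candidates)
    full = None
    if len(candidates) + 1 < len(features):
        full = _try_fit(features, labels, sorted(candidates))
    if full is None:
        fwd = forward_select(features, labels, candidates)
        msg = "full model unfittable; backward elimination fell back to forward selection"
        logger.warning(msg)
        return SelectionResult("backward", fwd.selected, fwd.model,
                               fwd.aic_trajectory, [msg])
    current = sorted(candidates)
    model = full
    trajectory = [model.aic]
    while current:
        move = _best_move(features, labels, current,
                          [(v, [w for w in current if w != v]) for v in current])
        if move is None or move[2].aic >= model.aic - _AIC_EPS:
            break
        current, model = move[1], move[2]
        trajectory.append(model.aic)
    return SelectionResult("backward", current, model, trajectory, [])


def stepwise_select(features: pd.DataFrame, labels, candidates: list[str]) -> SelectionResult:
    """Bidirectional: alternate additions and removals until no move lowers AIC."""
    candidates = drop_degenerate(features, candidates)
    current: list[str] = []
    model = fit_logistic(features, labels, current)
    trajectory = [model.aic]
    while True:
        moves = [(v, current + [v]) for v in candidates if v not in current]
        moves += [(v, [w for w in current if w != v]) for v in current]
        move = _best_move(features, labels, current, moves)
        if move is None or move[2].aic >= model.aic - _AIC_EPS:
            break
        current, model = sorted(move[1]), move[2]
        trajectory.append(model.aic)
    return SelectionResult("stepwise", current, model, trajectory, [])


def significance_filter(
    features: pd.DataFrame, labels, model: FittedModel, alpha: float = 0.05
) -> FittedModel:
    """Optional post-hoc filter: iteratively drop the least significant
    variable with Wald P >= ``alpha`` and refit.

    Off by default in the pipeline — AIC minimization is the operative
    retention rule, and published models of this kind keep P ~ 0.06-0.11
    terms — but available for sensitivity analyses.
    """
    current = list(model.variables)
    fit = model
    while current:
        p = fit.p_values.drop("(intercept)")
        worst = p.idxmax()
        if p[worst] < alpha:
            break
        current.remove(worst)
        fit = fit_logistic(features, labels, current)
    return fit


SEARCH_METHODS = {
    "forward": forward_select,
    "backward": backward_eliminate,
    "stepwise": stepwise_select,
}


def select_best(results: list[SelectionResult]) -> SelectionResult:
    """Winner across searches: minimum AIC, then fewer parameters, then name."""
    if not results:
        raise ValueError("no fitted models to select from")

    def key(r: SelectionResult):
        return (round(r.model.aic / _AIC_EPS) * _AIC_EPS, r.model.k,
                tuple(sorted(r.selected)))

    return min(results, key=key)


@dataclass
class EPVAdvisory:
    """Events-per-variable adequacy advisory (10 events per parameter)."""

    n_events: int
    n_params: int
    ok: bool
    message: str


def epv_check(n_events: int, n_params: int) -> EPVAdvisory:
    """Warn (never block) when fewer than 10 events per estimated parameter."""
    if n_events <= 0:
        msg = "no events in stratum; any model is unsupported"
        ok = False
    elif n_params > n_events / 10.0:
        msg = (f"events-per-variable low: {n_params} parameters for {n_events} "
               f"events (>{n_events / 10.0:.1f} allowed by the 1:10 rule)")
        ok = False
    else:
        msg = f"adequate: {n_params} parameters for {n_events} events"
        ok = True
    if not ok:
        logger.warning("EPV advisory: %s", msg)
    return EPVAdvisory(n_events=n_events, n_params=n_params, ok=ok, message=msg)
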