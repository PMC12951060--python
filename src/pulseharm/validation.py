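"""Model validation: ROC discrimination, calibration, bootstrap internal validity.

* AUC is computed as the Mann-Whitney pairwise concordance (ties count 1/2),
  which equals the trapezoidal area under the empirical ROC curve; ROC points
  come from scikit-learn.
* The Hosmer-Lemeshow statistic groups subjects into equal-count deciles of
  predicted risk and compares observed with expected event counts;
  df = groups - 2 (in-sample convention), P from the chi-square upper tail.
* Bootstrap internal validation redraws subjects with replacement, refits the
  coefficients of the FIXED selected-variable set on each resample, scores
  the original sample, and reports the mean AUC with a 2.5-97.5 percentile
  interval over 2000 resamples by default.  Variables are not re-selected
  inside resamples, so residual selection optimism is not captured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata
from sklearn.metrics import roc_curve

from pulseharm.errors import SeparationError, SingularDesignError
from pulseharm.selection import FittedModel, fit_logistic

_HL_EPS = 1e-10


def _capped_scores(
    train: pd.DataFrame, y_train: np.ndarray, variables: list[str],
    score_on: pd.DataFrame,
) -> np.ndarray:
    """Linear scores from a weakly L2-capped logistic fit.

    Used only when the unpenalized resample fit separates: the tiny ridge
    penalty keeps the coefficients finite while preserving the score ordering
    (AUC is rank-based, so the cap does not bias discrimination).
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    X = train[variables].to_numpy(dtype=float)
    clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=1000)
    with warnings.catch_warnings():
        # near-separated resamples legitimately stop at the iteration cap
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y_train)
    return clf.decision_function(score_on[variables].to_numpy(dtype=float))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise concordance AUC: P(score_event > score_nonevent) + P(tie)/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Ordered (FPR, TPR) pairs from (0,0) to (1,1)."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])


def trapezoidal_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by trapezoidal integration of the ROC curve (cross-check route)."""
    pts = roc_points(scores, labels)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def _risk_groups(probabilities: np.ndarray, n_groups: int) -> list[np.ndarray]:
    """Equal-count groups by ascending predicted risk; ties go to the lower
    group via stable sorting."""
    order = np.argsort(probabilities, kind="stable")
    return [g for g in np.array_split(order, n_groups) if g.size > 0]


@dataclass
class HosmerLemeshowResult:
    statistic: float
    df: int
    p_value: float
    #: groups whose mean predicted risk was exactly 0 or 1 (epsilon-guarded)
    degenerate_groups: tuple[int, ...] = ()


def hosmer_lemeshow(
    probabilities: np.ndarray, labels: np.ndarray, n_groups: int = 10
) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow chi-square goodness-of-fit over risk deciles.

    statistic = sum_g (O_g - E_g)^2 / (n_g * pbar_g * (1 - pbar_g)) with
    O_g observed events, E_g = n_g * pbar_g expected events and pbar_g the
    group's mean predicted probability.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(p) < 2 * n_groups:
        raise ValueError(f"need >= {2 * n_groups} subjects for {n_groups} groups")
    stat = 0.0
    degenerate = []
    for g, idx in enumerate(_risk_groups(p, n_groups)):
        n_g = idx.size
        pbar = float(p[idx].mean())
        obs = float(y[idx].sum())
        exp = n_g * pbar
        denom = n_g * pbar * (1.0 - pbar)
        if denom <= _HL_EPS:
            degenerate.append(g)
            denom = _HL_EPS
        stat += (obs - exp) ** 2 / denom
    df = n_groups - 2
    return HosmerLemeshowResult(
        statistic=float(stat), df=df, p_value=float(chi2.sf(stat, df)),
        degenerate_groups=tuple(degenerate),
    )


def calibration_curve(
    probabilities: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Per risk-decile (mean predicted probability, observed event rate)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    groups = _risk_groups(p, n_bins)
    return np.array([[p[idx].mean(), y[idx].mean()] for idx in groups])


@dataclass
class BootstrapResult:
    mean_auc: float
    ci: tuple[float, float]
    n_resamples: int
    n_degenerate: int
    aucs: np.ndarray = field(repr=False)

    @property
    def degenerate_warning(self) -> bool:
        return self.n_degenerate > 0.1 * self.n_resamples


def bootstrap_validate(
    features: pd.DataFrame,
    labels: np.ndarray,
    variables: list[str],
    n_resamples: int = 2000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap internal validation of a fixed variable set.

    Each resample draws n subjects with replacement, refits the coefficients,
    and scores the ORIGINAL sample; resamples with a single outcome class are
    redrawn (up to 20 tries) and counted as degenerate, while a resample fit
    that separates is scored through a weakly capped fit (also counted as
    degenerate).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=float)
    n = len(y)
    aucs = np.empty(n_resamples)
    n_degenerate = 0
    for r in range(n_resamples):
        scores = None
        for _ in range(20):
            idx = rng.integers(0, n, n)
            y_b = y[idx]
            if y_b.sum() in (0, len(y_b)):
                n_degenerate += 1
                continue
            boot = features.iloc[idx].reset_index(drop=True)
            try:
                scores = fit_logistic(boot, y_b, variables).predict(features)
            except (SeparationError, SingularDesignError):
                n_degenerate += 1
                scores = _capped_scores(boot, y_b, variables, features)
            break
        if scores is None:
            raise RuntimeError("could not obtain a fittable bootstrap resample")
        aucs[r] = auc(scores, y)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return BootstrapResult(
        mean_auc=float(aucs.mean()), ci=(float(lo), float(hi)),
        n_resamples=n_resamples, n_degenerate=n_degenerate, aucs=aucs,
    )


@dataclass
class ValidationReport:
    """Discrimination + calibration + internal-validity summary of one model."""

    auc: float
    roc_points: np.ndarray
    hl: HosmerLemeshowResult
    bootstrap: BootstrapResult | None
    calibration_points: np.ndarray

    def to_dict(self) -> dict:
        out = {
            "auc": float(self.auc),
            "roc_points": self.roc_points.tolist(),
            "hosmer_lemeshow": {
                "statistic": self.hl.statistic,
                "df": self.hl.df,
                "p_value": self.hl.p_value,
                "degenerate_groups": list(self.hl.degenerate_groups),
            },
            "calibration_points": self.calibration_points.tolist(),
        }
        if self.bootstrap is not None:
            out["bootstrap"] = {
                "mean_auc": self.bootstrap.mean_auc,
                "ci": list(self.bootstrap.ci),
                "n_resamples": self.bootstrap.n_resamples,
                "n_degenerate": self.bootstrap.n_degenerate,
            }
        return out


def validate_model(
    model: FittedModel,
    features: pd.DataFrame,
    labels: np.ndarray,
    n_resamples: int = 2000,
    n_groups: int = 10,
    seed: int = 0,
) -> ValidationReport:
    """Full validation of a fitted model on its development sample."""
    y = np.asarray(labels, dtype=float)
    probs = model.predict(features)
    return ValidationReport(
        auc=auc(probs, y),
        roc_points=roc_points(probs, y),
        hl=hosmer_lemeshow(probs, y, n_groups=n_groups),
        bootstrap=bootstrap_validate(
            features, y, model.variables, n_resamples=n_resamples, seed=seed
        ) if n_resamples > 0 else None,
        calibration_points=calibration_curve(probs, y, n_bins=n_groups),
    )
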