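"""Subject-level computations: logistic ML fitting, empirical c, group moments.

These are the estimation counterparts of :mod:`cstat.analytic`: given a
two-column dataset (continuous covariate ``x``, binary outcome ``y``) they
produce the empirical c-statistic of the fitted univariate logistic model
and the two moment-based predictions of it.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from .analytic import BinormalParams, EqualVarianceSpec, auc_binormal, auc_equal_variance

__all__ = [
    "SubjectData",
    "LogisticFit",
    "GroupMoments",
    "SeparationWarning",
    "fit_logistic",
    "concordance",
    "empirical_c_of_model",
    "group_moments",
    "sample_skewness",
    "predicted_c_formula1",
    "predicted_c_formula2",
    "read_subject_csv",
    "evaluate_dataset",
]

logger = logging.getLogger(__name__)

# IRLS convergence: max |score component| on the standardized scale
_SCORE_TOL = 1e-8
_MAX_ITER = 50
# |coefficient| beyond this on standardized data signals (quasi-)separation
_SEPARATION_BOUND = 20.0


class SeparationWarning(UserWarning):
    """Raised as a warning when a logistic fit shows complete or quasi-complete separation."""


@dataclass(frozen=True, eq=False)
class SubjectData:
    """Subject-level covariate/outcome pairs.

    ``x`` is the continuous covariate, one entry per subject; ``y`` the
    binary outcome indicator (0/1).  Arrays are validated and copied on
    construction.
    """

    x: np.ndarray
    y: np.ndarray

    def __init__(self, x, y) -> None:
        x = np.asarray(x, dtype=float).ravel()
        y_arr = np.asarray(y).ravel()
        if x.shape != y_arr.shape:
            raise ValueError(f"x and y must have equal length, got {x.size} and {y_arr.size}")
        if x.size < 2:
            raise ValueError("need at least 2 subjects")
        if not np.all(np.isfinite(x)):
            raise ValueError("x contains non-finite values")
        if not np.isin(y_arr, (0, 1)).all():
            raise ValueError("y must contain only 0 and 1")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y_arr.astype(np.int8))

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def n_affected(self) -> int:
        return int(self.y.sum())

    def require_both_classes(self) -> None:
        n1 = self.n_affected
        if n1 == 0 or n1 == self.n:
            raise ValueError("degenerate outcome: y contains a single class")


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood estimates of the univariate logistic model logit(p) = b0 + b1*x."""

    intercept: float
    slope: float
    converged: bool
    n_iterations: int
    separation_detected: bool

    def predict_proba(self, x) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class GroupMoments:
    """Per-outcome-group sample moments of the covariate.

    Variances use the n-1 denominator.  Skewness is the moment estimator
    ``b1 = g1 * ((n-1)/n)^{3/2}`` (see :func:`sample_skewness`).  Moments
    that are undefined for the group size (variance below 2 subjects,
    skewness below 3) are NaN, never 0.
    """

    n_affected: int
    n_unaffected: int
    mean_affected: float
    mean_unaffected: float
    var_affected: float
    var_unaffected: float
    skew_affected: float
    skew_unaffected: float
    var_combined: float


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def fit_logistic(data: SubjectData) -> LogisticFit:
    """Fit logit(p) = b0 + b1*x by Newton-Raphson (IRLS) maximum likelihood.

    Converges when every component of the score vector (on internally
    standardized x, for conditioning) falls below 1e-8, within 50
    iterations, with step-halving when a step would reduce the likelihood.
    Complete or quasi-complete separation is flagged — not raised — when a
    standardized coefficient exceeds 20 or the likelihood fails to
    stabilize; the returned estimates are then the last iterate and should
    be treated as diverging.
    """
    data.require_both_classes()
    x, y = data.x, data.y.astype(float)
    x_mean = float(x.mean())
    x_sd = float(x.std(ddof=1))
    if x_sd == 0.0:
        raise ValueError("constant covariate: slope is unidentifiable")
    z = (x - x_mean) / x_sd

    X = np.column_stack([np.ones_like(z), z])
    beta = np.zeros(2)
    beta[0] = math.log(y.mean() / (1.0 - y.mean()))  # intercept-only start
    ll = _loglik(X @ beta, y)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = X @ beta
        p = expit(eta)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            break
        w = p * (1.0 - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            break
        # step-halving guards against overshooting; the slack keeps rounding
        # noise in the log-likelihood from rejecting the final Newton steps
        slack = 1e-10 * (abs(ll) + 1.0)
        new_beta = beta + step
        new_ll = _loglik(X @ new_beta, y)
        halvings = 0
        while new_ll < ll - slack and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = _loglik(X @ new_beta, y)
            halvings += 1
        beta, ll = new_beta, new_ll

    separation = bool(np.max(np.abs(beta)) > _SEPARATION_BOUND or not converged)
    if separation:
        warnings.warn(
            "logistic fit shows signs of complete or quasi-complete separation; "
            "coefficient estimates diverge",
            SeparationWarning,
            stacklevel=2,
        )

    slope = beta[1] / x_sd
    intercept = beta[0] - slope * x_mean
    return LogisticFit(
        intercept=float(intercept),
        slope=float(slope),
        converged=converged,
        n_iterations=it,
        separation_detected=separation,
    )


def concordance(data: SubjectData, scores) -> float:
    """All-pairs concordance of ``scores`` with the binary outcome.

    Over every (affected, unaffected) pair, a pair scores 1 when the
    affected subject has the higher score, 0.5 on a tie and 0 otherwise;
    the result is the proportion over all such pairs.  Computed via the
    Wilcoxon rank-sum identity with midranks, which credits ties exactly
    0.5 each, and is invariant under strictly increasing transformations
    of the scores.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.shape != data.y.shape:
        raise ValueError("scores must have one entry per subject")
    data.require_both_classes()
    n1 = data.n_affected
    n0 = data.n - n1
    ranks = rankdata(scores)  # midranks
    rank_sum_affected = float(ranks[data.y == 1].sum())
    u = rank_sum_affected - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def empirical_c_of_model(data: SubjectData) -> tuple[float, LogisticFit]:
    """Fit the univariate logistic model and return the c-statistic of its fitted probabilities."""
    fit = fit_logistic(data)
    return concordance(data, fit.predict_proba(data.x)), fit


def sample_skewness(values: np.ndarray, estimator: str = "b1") -> float:
    """Moment-based sample skewness.

    ``"g1"`` is the plain moment ratio ``m3 / m2^{3/2}``; the default
    ``"b1" = g1 * ((n-1)/n)^{3/2}`` matches the default of the skewness
    helpers common in statistical software.  Returns NaN below 3
    observations or for constant input.
    """
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    if n < 3:
        return math.nan
    d = v - v.mean()
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        return math.nan
    g1 = float(np.mean(d**3)) / m2**1.5
    if estimator == "g1":
        return g1
    if estimator == "b1":
        return g1 * ((n - 1) / n) ** 1.5
    raise ValueError(f"unknown skewness estimator {estimator!r}")


def group_moments(data: SubjectData, skew_estimator: str = "b1") -> GroupMoments:
    """Mean, variance (n-1) and skewness of x within each outcome group, plus the combined variance."""
    data.require_both_classes()
    xa = data.x[data.y == 1]
    xu = data.x[data.y == 0]

    def _var(v: np.ndarray) -> float:
        return float(np.var(v, ddof=1)) if v.size >= 2 else math.nan

    return GroupMoments(
        n_affected=xa.size,
        n_unaffected=xu.size,
        mean_affected=float(xa.mean()),
        mean_unaffected=float(xu.mean()),
        var_affected=_var(xa),
        var_unaffected=_var(xu),
        skew_affected=sample_skewness(xa, skew_estimator),
        skew_unaffected=sample_skewness(xu, skew_estimator),
        var_combined=float(np.var(data.x, ddof=1)),
    )


def predicted_c_formula1(data: SubjectData) -> float:
    """Moment-based prediction: estimate group means/SDs, apply the unequal-variance formula."""
    m = group_moments(data)
    if not (math.isfinite(m.var_affected) and math.isfinite(m.var_unaffected)):
        raise ValueError("group variance undefined: each outcome group needs at least 2 subjects")
    if m.var_affected <= 0 or m.var_unaffected <= 0:
        raise ValueError("group variance is zero: covariate constant within a group")
    params = BinormalParams(
        mu_affected=m.mean_affected,
        mu_unaffected=m.mean_unaffected,
        sd_affected=math.sqrt(m.var_affected),
        sd_unaffected=math.sqrt(m.var_unaffected),
    )
    return auc_binormal(params)


def read_subject_csv(path) -> SubjectData:
    """Load subject-level data from a headered CSV with columns ``x`` and ``y``."""
    import pandas as pd

    frame = pd.read_csv(path)
    missing = {"x", "y"} - set(frame.columns)
    if missing:
        raise ValueError(f"input CSV lacks required column(s): {sorted(missing)}")
    return SubjectData(frame["x"].to_numpy(), frame["y"].to_numpy())


def evaluate_dataset(data: SubjectData) -> dict:
    """Empirical c plus both closed-form predictions for one dataset.

    Returns a flat record: n, n_affected, c_empirical, c_formula1,
    c_formula2, the estimated standardized difference d, and the group
    skewnesses — the one-row report the ``evaluate`` CLI writes.
    """
    c_emp, fit = empirical_c_of_model(data)
    m = group_moments(data)
    d = math.nan
    if m.var_affected > 0 and m.var_unaffected > 0:
        d = (m.mean_affected - m.mean_unaffected) / math.sqrt(
            (m.var_affected + m.var_unaffected) / 2.0
        )
    return {
        "n": data.n,
        "n_affected": data.n_affected,
        "c_empirical": c_emp,
        "c_formula1": predicted_c_formula1(data),
        "c_formula2": predicted_c_formula2(data, fit=fit),
        "d": d,
        "skew_affected": m.skew_affected,
        "skew_unaffected": m.skew_unaffected,
    }


def predicted_c_formula2(data: SubjectData, fit: LogisticFit | None = None) -> float:
    """Slope-based prediction: fitted log-odds ratio times the combined-sample SD.

    The common variance the equal-variance formula needs is estimated as
    the variance of x in the combined sample of both groups.  Pass ``fit``
    to reuse an existing fit instead of refitting.
    """
    if fit is None:
        fit = fit_logistic(data)
    sigma = math.sqrt(float(np.var(data.x, ddof=1)))
    return auc_equal_variance(EqualVarianceSpec(sigma=sigma, beta=fit.slope))
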