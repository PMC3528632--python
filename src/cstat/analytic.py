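"""Closed-form predictions of the concordance statistic under binormality.

When a continuous covariate X is normally distributed both in subjects with
the outcome (mean ``mu_A``, SD ``sigma_A``) and in subjects without it
(mean ``mu_U``, SD ``sigma_U``), the c-statistic (equivalently, the area
under the ROC curve) of the univariate logistic model for the outcome has
the closed form

    c = Phi( (mu_A - mu_U) / sqrt(sigma_A^2 + sigma_U^2) ) = Phi(d / sqrt(2))

where ``Phi`` is the standard normal CDF and ``d`` is the standardized
difference (Cohen's effect size) with the quadratic-mean pooled denominator
``sqrt((sigma_A^2 + sigma_U^2)/2)``.

In the equal-variance special case (common SD ``sigma``), the discriminant
analysis identity ``beta = (mu_A - mu_U)/sigma^2`` reduces this to

    c = Phi( sigma * beta / sqrt(2) )

so the discrimination of a covariate is governed jointly by its log-odds
ratio ``beta`` and the heterogeneity ``sigma`` of the population: the same
odds ratio yields a higher c-statistic in a more heterogeneous population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy.stats import norm

__all__ = [
    "BinormalParams",
    "EqualVarianceSpec",
    "auc_binormal",
    "standardized_difference",
    "auc_equal_variance",
    "auc_from_linear_predictor_moments",
    "somers_d_from_c",
]

_SQRT2 = math.sqrt(2.0)

# Phi saturates to 0.0/1.0 in double precision for |z| beyond ~8.3 (39);
# nudge back one representable value to honour the open-interval contract
_LO = math.nextafter(0.0, 1.0)
_HI = math.nextafter(1.0, 0.0)


def _open_unit(p: float) -> float:
    return min(max(float(p), _LO), _HI)


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def _require_positive(name: str, value: float) -> float:
    value = _require_finite(name, value)
    if value <= 0.0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")
    return value


@dataclass(frozen=True)
class BinormalParams:
    """Group-wise moments of a covariate in affected and unaffected subjects.

    Parameters
    ----------
    mu_affected, mu_unaffected:
        Means of the covariate in subjects with and without the outcome,
        in covariate units.
    sd_affected, sd_unaffected:
        Standard deviations in the two groups; must be strictly positive.
    """

    mu_affected: float
    mu_unaffected: float
    sd_affected: float
    sd_unaffected: float

    def __post_init__(self) -> None:
        _require_finite("mu_affected", self.mu_affected)
        _require_finite("mu_unaffected", self.mu_unaffected)
        _require_positive("sd_affected", self.sd_affected)
        _require_positive("sd_unaffected", self.sd_unaffected)

    @property
    def mean_difference(self) -> float:
        return self.mu_affected - self.mu_unaffected


@dataclass(frozen=True)
class EqualVarianceSpec:
    """Common covariate SD plus the log-odds ratio relating it to the outcome.

    ``beta`` is the logistic slope: a one-unit increase in the covariate
    multiplies the outcome odds by ``exp(beta)``.
    """

    sigma: float
    beta: float

    def __post_init__(self) -> None:
        _require_positive("sigma", self.sigma)
        _require_finite("beta", self.beta)


def auc_binormal(params: BinormalParams) -> float:
    """Predicted c-statistic with no restriction on the two group variances.

    Returns ``Phi((mu_A - mu_U) / sqrt(sd_A^2 + sd_U^2))``, strictly
    increasing in the mean difference and always inside (0, 1).
    """
    denom = math.hypot(params.sd_affected, params.sd_unaffected)
    return _open_unit(norm.cdf(params.mean_difference / denom))


def standardized_difference(params: BinormalParams) -> float:
    """Standardized difference d of the covariate between outcome groups.

    Uses the quadratic-mean pooled SD ``sqrt((sd_A^2 + sd_U^2)/2)``, the
    denominator under which the binormal c-statistic is exactly
    ``Phi(d/sqrt(2))``.  Sign follows ``mu_affected - mu_unaffected``.
    """
    pooled = math.sqrt((params.sd_affected**2 + params.sd_unaffected**2) / 2.0)
    return params.mean_difference / pooled


def auc_equal_variance(spec: EqualVarianceSpec) -> float:
    """Predicted c-statistic in the equal-variance case: Phi(sigma*beta/sqrt(2)).

    Equals :func:`auc_binormal` evaluated at a mean difference of
    ``beta * sigma**2`` with common SD ``sigma`` (the discriminant identity
    ``beta = (mu_A - mu_U)/sigma^2``).  Negative ``beta`` deliberately yields
    values below 0.5; callers wanting direction-free discrimination should
    take ``max(c, 1 - c)``.
    """
    return _open_unit(norm.cdf(spec.sigma * spec.beta / _SQRT2))


def auc_from_linear_predictor_moments(
    params: BinormalParams,
    mode: Literal["general", "equal_variance"] = "general",
    group_weights: tuple[float, float] | None = None,
) -> float:
    """Predicted c-statistic from the moments of a model's linear predictor.

    Any multivariable logistic model reduces to a single continuous score —
    its linear predictor — whose regression coefficient is 1 by construction
    when the outcome is regressed on it alone.  Feeding the group-wise
    moments of the linear predictor here therefore predicts the c-statistic
    of the full model.

    ``mode="general"`` applies the unequal-variance formula directly.
    ``mode="equal_variance"`` applies the equal-variance formula with
    ``beta = 1``; the single SD it needs is the combined-population SD,
    reconstructed from the group moments by the law of total variance with
    the supplied ``group_weights`` (affected, unaffected; default equal).
    """
    if mode == "general":
        return auc_binormal(params)
    if mode != "equal_variance":
        raise ValueError(f"mode must be 'general' or 'equal_variance', got {mode!r}")

    if group_weights is None:
        w_a, w_u = 0.5, 0.5
    else:
        w_a, w_u = (float(w) for w in group_weights)
        if w_a < 0 or w_u < 0 or w_a + w_u <= 0:
            raise ValueError("group_weights must be non-negative and not both zero")
        total = w_a + w_u
        w_a, w_u = w_a / total, w_u / total

    grand_mean = w_a * params.mu_affected + w_u * params.mu_unaffected
    var_combined = (
        w_a * params.sd_affected**2
        + w_u * params.sd_unaffected**2
        + w_a * (params.mu_affected - grand_mean) ** 2
        + w_u * (params.mu_unaffected - grand_mean) ** 2
    )
    return auc_equal_variance(EqualVarianceSpec(sigma=math.sqrt(var_combined), beta=1.0))


def somers_d_from_c(c: float) -> float:
    """Somers' Dxy rank correlation implied by a c-statistic: Dxy = 2(c - 0.5)."""
    c = _require_finite("c", c)
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"c must lie in [0, 1], got {c!r}")
    return 2.0 * (c - 0.5)


def c_from_somers_d(dxy: float) -> float:
    """Inverse of :func:`somers_d_from_c`: c = Dxy/2 + 0.5."""
    dxy = _require_finite("dxy", dxy)
    if not -1.0 <= dxy <= 1.0:
        raise ValueError(f"Dxy must lie in [-1, 1], got {dxy!r}")
    return dxy / 2.0 + 0.5
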