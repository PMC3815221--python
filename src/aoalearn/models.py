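"""Closed-form layer for age-of-acquisition (AoA) distributions.

A learner acquires a word once a threshold number of relevant events has
been sampled from a nonhomogeneous point process whose cumulative intensity
grows as a power of age, ``Lambda(t) = base_rate * t**rate_exponent``.  Over
a population of learners the acquisition age then follows a generalized
gamma law whose named special cases are:

* ``gamma`` — constant sampling rate (``rate_exponent == 1``), threshold
  ``accumulation`` events: cumulative learning.
* ``weibull`` — single-event threshold (``accumulation == 1``) under a
  time-varying rate: rate-change learning.
* ``weibull_gamma`` — the full family with both mechanisms free.

A two-parameter logistic S-curve is kept alongside as the conventional
growth-curve alternative.

All distribution functions are vectorized over the age argument and return
scalars for scalar input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import special

__all__ = [
    "ModelKind",
    "HazardShape",
    "LearningParams",
    "LogisticParams",
    "cumulative_intensity",
    "aoa_cdf",
    "aoa_pdf",
    "aoa_hazard",
    "aoa_mean",
    "aoa_quantile",
    "classify_hazard_shape",
]

#: relative tolerance used when deciding whether a parameter sits exactly on
#: a sub-family boundary (e.g. rate_exponent == 1).
_FAMILY_RTOL = 1e-9


class ModelKind(str, Enum):
    """The four candidate AoA models."""

    WEIBULL = "weibull"
    GAMMA = "gamma"
    WEIBULL_GAMMA = "weibull_gamma"
    LOGISTIC = "logistic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def n_params(self) -> int:
        """Number of free parameters of the family (BIC penalty term)."""
        return 3 if self is ModelKind.WEIBULL_GAMMA else 2


class HazardShape(str, Enum):
    """Qualitative shape of an accumulator model's hazard function."""

    CONSTANT = "constant"
    MONOTONE_INCREASING = "monotone_increasing"
    MONOTONE_DECREASING = "monotone_decreasing"
    PEAKED = "peaked"
    #: decreasing-then-increasing; arises only for accumulation < 1 with an
    #: accelerating rate and is outside the named model prototypes.
    BATHTUB = "bathtub"


@dataclass(frozen=True)
class LearningParams:
    """Parameters of one accumulator model.

    Attributes
    ----------
    accumulation:
        Number of sampled events needed to acquire the word (real > 0; an
        integer value recovers the literal counting process).
    rate_exponent:
        Exponent of the power-law sampling intensity. 1 means a constant
        rate, > 1 accelerating, < 1 decelerating.
    base_rate:
        Scale of the sampling intensity, units month**(-rate_exponent).
    """

    accumulation: float
    rate_exponent: float
    base_rate: float

    def __post_init__(self) -> None:
        for name in ("accumulation", "rate_exponent", "base_rate"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be a finite positive real, got {value!r}")

    @property
    def kind(self) -> ModelKind:
        """Most specific family this parameter triple belongs to."""
        if math.isclose(self.rate_exponent, 1.0, rel_tol=_FAMILY_RTOL):
            return ModelKind.GAMMA
        if math.isclose(self.accumulation, 1.0, rel_tol=_FAMILY_RTOL):
            return ModelKind.WEIBULL
        return ModelKind.WEIBULL_GAMMA


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the logistic alternative: F(t) = expit(slope*t - intercept)."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and self.slope > 0):
            raise ValueError(f"slope must be a finite positive real, got {self.slope!r}")
        if not math.isfinite(self.intercept):
            raise ValueError(f"intercept must be finite, got {self.intercept!r}")

    @property
    def kind(self) -> ModelKind:
        return ModelKind.LOGISTIC


Params = LearningParams | LogisticParams


def _check_kind(kind: ModelKind, params: Params) -> None:
    kind = ModelKind(kind)
    if kind is ModelKind.LOGISTIC:
        if not isinstance(params, LogisticParams):
            raise TypeError("logistic kind requires LogisticParams")
        return
    if not isinstance(params, LearningParams):
        raise TypeError(f"{kind.value} kind requires LearningParams")
    if kind is ModelKind.GAMMA and not math.isclose(
        params.rate_exponent, 1.0, rel_tol=_FAMILY_RTOL
    ):
        raise ValueError("gamma kind requires rate_exponent == 1")
    if kind is ModelKind.WEIBULL and not math.isclose(
        params.accumulation, 1.0, rel_tol=_FAMILY_RTOL
    ):
        raise ValueError("weibull kind requires accumulation == 1")


def _as_age(t, *, allow_negative: bool = False, strict_positive: bool = False):
    arr = np.asarray(t, dtype=float)
    if not allow_negative and np.any(arr < 0):
        raise ValueError("age must be non-negative")
    if strict_positive and np.any(arr <= 0):
        raise ValueError("age must be strictly positive")
    return arr


def _maybe_scalar(arr, t):
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(arr)
    return arr


def cumulative_intensity(params: LearningParams, t):
    """Expected number of sampled events by age ``t`` (months).

    ``Lambda(t) = base_rate * t**rate_exponent``; reduces to a linear
    accrual ``base_rate * t`` for a constant rate.
    """
    if not isinstance(params, LearningParams):
        raise TypeError("cumulative_intensity requires LearningParams")
    arr = _as_age(t)
    out = params.base_rate * np.power(arr, params.rate_exponent)
    return _maybe_scalar(out, t)


def aoa_cdf(kind: ModelKind, params: Params, t):
    """Probability that a word is acquired by age ``t``.

    For accumulator kinds this is the probability that the threshold-th
    event has occurred by ``t``: the regularized lower incomplete gamma
    function of (accumulation, Lambda(t)).
    """
    _check_kind(kind, params)
    if ModelKind(kind) is ModelKind.LOGISTIC:
        arr = np.asarray(t, dtype=float)
        out = special.expit(params.slope * arr - params.intercept)
        return _maybe_scalar(out, t)
    arr = _as_age(t)
    with np.errstate(over="ignore"):
        out = special.gammainc(
            params.accumulation, params.base_rate * np.power(arr, params.rate_exponent)
        )
    return _maybe_scalar(out, t)


def _aoa_sf(kind: ModelKind, params: Params, t):
    """Survival function 1 - CDF, computed without cancellation."""
    if ModelKind(kind) is ModelKind.LOGISTIC:
        arr = np.asarray(t, dtype=float)
        return special.expit(-(params.slope * arr - params.intercept))
    arr = _as_age(t)
    with np.errstate(over="ignore"):
        return special.gammaincc(
            params.accumulation, params.base_rate * np.power(arr, params.rate_exponent)
        )


def aoa_pdf(kind: ModelKind, params: Params, t):
    """Density of the acquisition age at ``t`` (per month).

    Accumulator kinds use the generalized-gamma closed form evaluated in
    log space::

        f(t) = D * delta**N * t**(N*D - 1) * exp(-delta * t**D) / Gamma(N)

    with N = accumulation, D = rate_exponent, delta = base_rate.
    Raises for non-positive ages under the accumulator kinds.
    """
    _check_kind(kind, params)
    if ModelKind(kind) is ModelKind.LOGISTIC:
        arr = np.asarray(t, dtype=float)
        p = special.expit(params.slope * arr - params.intercept)
        return _maybe_scalar(params.slope * p * (1.0 - p), t)
    arr = _as_age(t, strict_positive=True)
    n, d, delta = params.accumulation, params.rate_exponent, params.base_rate
    log_f = (
        math.log(d)
        + n * math.log(delta)
        + (n * d - 1.0) * np.log(arr)
        - delta * np.power(arr, d)
        - special.gammaln(n)
    )
    return _maybe_scalar(np.exp(log_f), t)


def aoa_hazard(kind: ModelKind, params: Params, t):
    """Instantaneous acquisition rate among learners without the word at ``t``.

    ``hazard(t) = pdf(t) / (1 - cdf(t))``.  Where the survival probability
    underflows to zero the hazard is reported as ``+inf`` (sentinel for
    "everyone has acquired the word at this age to machine precision").
    """
    _check_kind(kind, params)
    f = np.asarray(aoa_pdf(kind, params, t), dtype=float)
    s = np.asarray(_aoa_sf(kind, params, t), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s > 0.0, f / np.where(s > 0.0, s, 1.0), np.inf)
    return _maybe_scalar(out, t)


def aoa_mean(kind: ModelKind, params: Params) -> float:
    """Expected acquisition age in months (closed form).

    Accumulator kinds: ``delta**(-1/D) * Gamma(N + 1/D) / Gamma(N)``;
    logistic: ``intercept / slope``.
    """
    _check_kind(kind, params)
    if ModelKind(kind) is ModelKind.LOGISTIC:
        return params.intercept / params.slope
    n, d, delta = params.accumulation, params.rate_exponent, params.base_rate
    return float(
        np.exp(special.gammaln(n + 1.0 / d) - special.gammaln(n) - math.log(delta) / d)
    )


def aoa_quantile(kind: ModelKind, params: Params, q):
    """Age (months) at which the CDF reaches probability ``q`` in (0, 1).

    Accumulator kinds invert through the regularized incomplete gamma
    inverse, ``t = (gammaincinv(N, q) / delta)**(1/D)``; the logistic model
    inverts in closed form.
    """
    _check_kind(kind, params)
    arr = np.asarray(q, dtype=float)
    if np.any((arr <= 0.0) | (arr >= 1.0)):
        raise ValueError("quantile level must lie strictly inside (0, 1)")
    if ModelKind(kind) is ModelKind.LOGISTIC:
        out = (params.intercept + special.logit(arr)) / params.slope
        return _maybe_scalar(out, q)
    n, d, delta = params.accumulation, params.rate_exponent, params.base_rate
    out = np.power(special.gammaincinv(n, arr) / delta, 1.0 / d)
    return _maybe_scalar(out, q)


def classify_hazard_shape(params: LearningParams, rtol: float = _FAMILY_RTOL) -> HazardShape:
    """Qualitative hazard shape of an accumulator model.

    The generalized-gamma hazard is governed by the rate exponent D and the
    product N*D (the power of age in the density):

    * D = 1, N*D = 1 — constant hazard (memoryless case);
    * D >= 1 and N*D >= 1 (not both 1) — monotone increasing;
    * D <= 1 and N*D <= 1 (not both 1) — monotone decreasing;
    * D < 1 and N*D > 1 — a single interior peak;
    * D > 1 and N*D < 1 — bathtub (decreasing then increasing).

    Boundary comparisons use relative tolerance ``rtol``; exact-tie cases
    (D = 1 with N > 1) fall in the monotone branches.
    """
    if not isinstance(params, LearningParams):
        raise TypeError("classify_hazard_shape requires LearningParams")
    d = params.rate_exponent
    nd = params.accumulation * d
    d_is_one = math.isclose(d, 1.0, rel_tol=rtol)
    nd_is_one = math.isclose(nd, 1.0, rel_tol=rtol)
    if d_is_one and nd_is_one:
        return HazardShape.CONSTANT
    if (d_is_one or d > 1.0) and (nd_is_one or nd > 1.0):
        return HazardShape.MONOTONE_INCREASING
    if (d_is_one or d < 1.0) and (nd_is_one or nd < 1.0):
        return HazardShape.MONOTONE_DECREASING
    if d < 1.0 and nd > 1.0:
        return HazardShape.PEAKED
    return HazardShape.BATHTUB
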