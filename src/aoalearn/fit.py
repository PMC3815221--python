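"""Per-word maximum-likelihood fitting and BIC model selection.

Each word's monthly acquisition proportions are fit by all four model
families.  The likelihood treats the proportion at each month as an
independent binomial observation with effective count ``n_children``:

    loglik = n * sum_m [ p_m * ln q_m + (1 - p_m) * ln(1 - q_m) ]

where ``q_m`` is the model CDF at month ``m`` clamped away from {0, 1}.
Monthly dependence (the same children are counted every month) is
deliberately ignored — a documented modelling approximation.  Model
comparison uses BIC = -2 * loglik + k * ln(n0) with n0 the number of
monthly observations per word (15), and smaller is better.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special

from .models import LearningParams, LogisticParams, ModelKind, Params, aoa_cdf

__all__ = ["FitConfig", "WordFit", "word_loglik", "bic", "fit_word", "select_model", "pick_winner"]

logger = logging.getLogger(__name__)

#: tie-break precedence when BIC values coincide: fewer parameters first,
#: then this fixed family order.
_TIE_ORDER = (ModelKind.GAMMA, ModelKind.WEIBULL, ModelKind.LOGISTIC, ModelKind.WEIBULL_GAMMA)


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the per-word optimizer."""

    n_children: int = 1000
    n0: int = 15
    epsilon: float = 1e-9  # clamp for model proportions before logs
    tol: float = 1e-8  # convergence tolerance on the objective
    grid_points: int = 4  # multistart grid points per free dimension
    n_refine: int = 3  # grid starts refined with a local search
    log10_bounds: tuple[float, float] = (-3.0, 4.0)  # accumulation and rate exponent
    # the base rate scales like (1/mean)**rate_exponent, so its box must be
    # much wider than the shape parameters' box
    log10_rate_bounds: tuple[float, float] = (-16.0, 6.0)
    intercept_bounds: tuple[float, float] = (-200.0, 400.0)
    max_iter: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon <= 1e-3):
            raise ValueError("epsilon must lie in (0, 1e-3]")
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        if self.n0 < 2:
            raise ValueError("n0 must be >= 2")


@dataclass(frozen=True)
class WordFit:
    """One fitted model for one word."""

    kind: ModelKind
    params: Params
    loglik: float
    bic: float
    converged: bool
    n_starts_used: int
    word: str | None = None
    message: str = ""


def word_loglik(kind: ModelKind, params: Params, p, months, config: FitConfig) -> float:
    """Binomial cross-entropy log-likelihood of one word's proportions."""
    p = np.asarray(p, dtype=float)
    months = np.asarray(months, dtype=float)
    if p.shape != months.shape:
        raise ValueError(f"proportions ({p.shape}) and months ({months.shape}) must align")
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("proportions must lie in [0, 1]")
    q = np.clip(aoa_cdf(kind, params, months), config.epsilon, 1.0 - config.epsilon)
    return float(config.n_children * np.sum(p * np.log(q) + (1.0 - p) * np.log1p(-q)))


def bic(loglik: float, k: int, n0: int) -> float:
    """Bayesian Information Criterion: -2*loglik + k*ln(n0); smaller is better."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n0 < 2:
        raise ValueError("n0 must be >= 2")
    return -2.0 * loglik + k * math.log(n0)


# ---------------------------------------------------------------------------
# internal parameterization: each kind is optimized over an unconstrained-ish
# box in transformed coordinates (natural log for positive parameters).

def _params_from_x(kind: ModelKind, x: np.ndarray) -> Params:
    if kind is ModelKind.GAMMA:
        return LearningParams(math.exp(x[0]), 1.0, math.exp(x[1]))
    if kind is ModelKind.WEIBULL:
        return LearningParams(1.0, math.exp(x[0]), math.exp(x[1]))
    if kind is ModelKind.WEIBULL_GAMMA:
        return LearningParams(math.exp(x[0]), math.exp(x[1]), math.exp(x[2]))
    return LogisticParams(slope=math.exp(x[0]), intercept=x[1])


def _x_from_params(kind: ModelKind, params: Params) -> np.ndarray:
    if kind is ModelKind.GAMMA:
        return np.log([params.accumulation, params.base_rate])
    if kind is ModelKind.WEIBULL:
        return np.log([params.rate_exponent, params.base_rate])
    if kind is ModelKind.WEIBULL_GAMMA:
        return np.log([params.accumulation, params.rate_exponent, params.base_rate])
    return np.array([math.log(params.slope), params.intercept])


def _bounds(kind: ModelKind, config: FitConfig) -> list[tuple[float, float]]:
    lo, hi = (b * math.log(10.0) for b in config.log10_bounds)
    rlo, rhi = (b * math.log(10.0) for b in config.log10_rate_bounds)
    if kind is ModelKind.WEIBULL_GAMMA:
        return [(lo, hi), (lo, hi), (rlo, rhi)]
    if kind is ModelKind.LOGISTIC:
        return [(lo, hi), config.intercept_bounds]
    return [(lo, hi), (rlo, rhi)]


def _clip_to_bounds(x: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo + 1e-9, hi - 1e-9)


def _empirical_moments(p: np.ndarray, months: np.ndarray) -> tuple[float, float]:
    """Crude mean/variance of the acquisition age from a proportion row.

    Probability mass increments between months are placed at interval
    midpoints; mass before the first month sits one month earlier and the
    censored tail five months after the last.  Only used to seed starts.
    """
    p = np.clip(p, 0.0, 1.0)
    w = np.maximum(np.diff(np.concatenate([[0.0], p])), 0.0)
    tail = max(1.0 - p[-1], 0.0)
    nodes = np.concatenate([[months[0] - 1.0], months[1:] - 0.5, [months[-1] + 5.0]])
    weights = np.concatenate([w[:1], w[1:], [tail]])
    total = weights.sum()
    if total <= 0:
        return float(months.mean()), float(np.var(months))
    mu = float(np.sum(weights * nodes) / total)
    var = float(np.sum(weights * (nodes - mu) ** 2) / total)
    return mu, max(var, 1e-6)


def _moment_start(kind: ModelKind, p: np.ndarray, months: np.ndarray) -> np.ndarray:
    mu, var = _empirical_moments(p, months)
    if kind is ModelKind.LOGISTIC:
        slope = math.pi / math.sqrt(3.0 * var)
        return np.array([math.log(slope), slope * mu])
    if kind is ModelKind.GAMMA:
        n = np.clip(mu * mu / var, 1e-3, 1e4)
        return np.log([n, n / mu])
    if kind is ModelKind.WEIBULL:
        cv = math.sqrt(var) / mu
        d = float(np.clip(cv**-1.086, 0.05, 50.0))  # standard Weibull CV approximation
        delta = (math.exp(special.gammaln(1.0 + 1.0 / d)) / mu) ** d
        return np.log([d, delta])
    n = np.clip(mu * mu / var, 1e-3, 1e4)
    return np.log([n, 1.0, n / mu])


def _log_rate_for_mean(n: float, d: float, mean: float) -> float:
    """log base_rate giving the accumulator model the requested mean age."""
    log_g = special.gammaln(n + 1.0 / d) - special.gammaln(n)
    return float(d * (log_g - math.log(mean)))


def _grid_starts(kind: ModelKind, p: np.ndarray, months: np.ndarray, config: FitConfig):
    """Multistart grid over the shape dimensions.

    The shape parameters (accumulation, rate exponent) are gridded on a log
    scale; at each grid point the base rate is solved so the model mean
    matches the row's empirical pseudo-mean, which keeps every start on the
    relevant scale regardless of how extreme the shape point is.
    """
    mu, _ = _empirical_moments(p, months)
    lo10, hi10 = config.log10_bounds
    axis = np.linspace(lo10, hi10, config.grid_points) * math.log(10.0)
    if kind is ModelKind.LOGISTIC:
        slope_axis = np.linspace(-2.0, 1.0, config.grid_points) * math.log(10.0)
        return [np.array([ls, math.exp(ls) * mu]) for ls in slope_axis]
    if kind is ModelKind.GAMMA:
        return [np.array([ln, _log_rate_for_mean(math.exp(ln), 1.0, mu)]) for ln in axis]
    if kind is ModelKind.WEIBULL:
        return [np.array([ld, _log_rate_for_mean(1.0, math.exp(ld), mu)]) for ld in axis]
    return [
        np.array([ln, ld, _log_rate_for_mean(math.exp(ln), math.exp(ld), mu)])
        for ln, ld in itertools.product(axis, repeat=2)
    ]


def fit_word(
    kind: ModelKind, p, months, config: FitConfig | None = None, word: str | None = None
) -> WordFit:
    """Maximum-likelihood fit of one model family to one word.

    Multistart strategy: the objective is evaluated on a coarse grid in the
    transformed parameter box plus a moment-matched start, and the best
    ``n_refine`` + 1 candidates are refined with bounded Nelder-Mead.
    Deterministic for a given configuration.  Rows with no proportion
    strictly inside (0, 1) are unidentifiable and come back flagged
    ``converged=False``.
    """
    config = config or FitConfig()
    kind = ModelKind(kind)
    p = np.asarray(p, dtype=float)
    months = np.asarray(months, dtype=float)
    if p.shape != months.shape:
        raise ValueError("proportions and months must align")

    bounds = _bounds(kind, config)

    def objective(x: np.ndarray) -> float:
        return -word_loglik(kind, _params_from_x(kind, x), p, months, config)

    degenerate = not np.any((p > 0.0) & (p < 1.0))
    start_pool = [_clip_to_bounds(s, bounds) for s in _grid_starts(kind, p, months, config)]
    start_pool.append(_clip_to_bounds(_moment_start(kind, p, months), bounds))
    scored = sorted(start_pool, key=objective)
    refine = scored[: config.n_refine + 1]

    best_x, best_val, any_success = None, np.inf, False
    for x0 in refine:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "fatol": config.tol,
                "xatol": 1e-6,
                "maxiter": config.max_iter,
                "maxfev": config.max_iter,
            },
        )
        if res.fun < best_val:
            best_x, best_val = res.x, res.fun
        any_success = any_success or bool(res.success)

    params = _params_from_x(kind, best_x)
    loglik = -best_val
    message = ""
    converged = any_success
    if degenerate:
        converged = False
        message = "degenerate row: no proportion strictly inside (0, 1); fit is a boundary artefact"
    elif not any_success:
        message = "no local search converged within iteration budget"
    return WordFit(
        kind=kind,
        params=params,
        loglik=loglik,
        bic=bic(loglik, kind.n_params, config.n0),
        converged=converged,
        n_starts_used=len(refine),
        word=word,
        message=message,
    )


def pick_winner(candidates: list[WordFit], atol: float = 1e-9) -> WordFit:
    """Smallest-BIC candidate; ties go to fewer parameters, then fixed order."""
    if not candidates:
        raise ValueError("no candidate fits to select among")
    best = min(c.bic for c in candidates)
    tied = [c for c in candidates if c.bic <= best + atol]
    return min(tied, key=lambda c: (c.kind.n_params, _TIE_ORDER.index(c.kind)))


def select_model(
    p, months, config: FitConfig | None = None, word: str | None = None
) -> tuple[WordFit, dict[ModelKind, WordFit]]:
    """Fit all four families to one word and pick the BIC winner.

    A family whose fit raises is excluded from the comparison with a logged
    warning; at least one family must fit.
    """
    config = config or FitConfig()
    candidates: dict[ModelKind, WordFit] = {}
    for kind in (ModelKind.GAMMA, ModelKind.WEIBULL, ModelKind.WEIBULL_GAMMA, ModelKind.LOGISTIC):
        try:
            candidates[kind] = fit_word(kind, p, months, config, word=word)
        except Exception as exc:  # noqa: BLE001 - a failed family is skipped, not fatal
            logger.warning("fit of %s failed for word %r: %s", kind.value, word, exc)
    if not candidates:
        raise RuntimeError(f"all model fits failed for word {word!r}")
    return pick_winner(list(candidates.values())), candidates
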