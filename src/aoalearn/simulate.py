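"""Stochastic accumulator simulator and synthetic norms generator.

Draws per-child acquisition ages from the accumulator process and converts
cohorts of ages into monthly acquisition-proportion tables of the same shape
as parent-report vocabulary norms (a word x month matrix of cumulative
proportions for ages 16-30 months).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .models import LearningParams, LogisticParams, ModelKind, Params, aoa_mean

__all__ = [
    "PopulationSpec",
    "SyntheticWordSpec",
    "NormsTable",
    "draw_acquisition_age",
    "draw_aoa",
    "simulate_norms",
    "solve_base_rate_for_mean",
    "make_mcdi_fixture",
    "make_selection_benchmark",
    "true_mean_aoa",
    "proportions_from_ages",
    "DEFAULT_MONTHS",
    "WORD_CLASSES",
    "CLASS_SIZES",
]

DEFAULT_MONTHS: tuple[int, ...] = tuple(range(16, 31))
#: classes entering class-based analyses
WORD_CLASSES: tuple[str, ...] = ("noun", "verb", "adjective", "closed")
#: fixture word counts per class; the two "other" words stand in for the
#: agrammatical checklist items kept out of class-based analyses, bringing
#: the total to 654.
CLASS_SIZES: dict[str, int] = {"noun": 389, "verb": 102, "adjective": 63, "closed": 98, "other": 2}

# default class-conditional mixture over true model kinds: closed-class
# words skew toward the rate-change (weibull) family, nouns toward the full
# accumulator family.
DEFAULT_KIND_MIXTURE: dict[str, dict[ModelKind, float]] = {
    "noun": {
        ModelKind.WEIBULL_GAMMA: 0.45,
        ModelKind.GAMMA: 0.35,
        ModelKind.WEIBULL: 0.10,
        ModelKind.LOGISTIC: 0.10,
    },
    "verb": {
        ModelKind.WEIBULL_GAMMA: 0.30,
        ModelKind.GAMMA: 0.45,
        ModelKind.WEIBULL: 0.10,
        ModelKind.LOGISTIC: 0.15,
    },
    "adjective": {
        ModelKind.WEIBULL_GAMMA: 0.25,
        ModelKind.GAMMA: 0.45,
        ModelKind.WEIBULL: 0.15,
        ModelKind.LOGISTIC: 0.15,
    },
    "closed": {
        ModelKind.WEIBULL_GAMMA: 0.15,
        ModelKind.GAMMA: 0.20,
        ModelKind.WEIBULL: 0.50,
        ModelKind.LOGISTIC: 0.15,
    },
    "other": {ModelKind.GAMMA: 0.5, ModelKind.WEIBULL: 0.5},
}


@dataclass(frozen=True)
class PopulationSpec:
    """Cohort used to turn per-child ages into monthly proportions."""

    n_children: int = 1000
    months: tuple[int, ...] = DEFAULT_MONTHS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        months = tuple(self.months)
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("months must be strictly increasing")
        object.__setattr__(self, "months", months)


@dataclass(frozen=True)
class SyntheticWordSpec:
    """Ground-truth generating model for one synthetic word."""

    word: str
    word_class: str
    kind: ModelKind
    params: Params = field(repr=False)

    def __post_init__(self) -> None:
        expected = LogisticParams if self.kind is ModelKind.LOGISTIC else LearningParams
        if not isinstance(self.params, expected):
            raise TypeError(f"{self.kind.value} word requires {expected.__name__}")


@dataclass(frozen=True)
class NormsTable:
    """Word x month matrix of cumulative acquisition proportions."""

    words: tuple[str, ...]
    word_classes: tuple[str, ...]
    months: tuple[int, ...]
    proportions: np.ndarray  # shape (n_words, n_months)
    n_children: int = 1000

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        if props.shape != (len(self.words), len(self.months)):
            raise ValueError("proportions shape must be (n_words, n_months)")
        if len(set(self.words)) != len(self.words):
            raise ValueError("duplicate word keys in norms table")
        if np.any((props < 0.0) | (props > 1.0)):
            raise ValueError("proportions must lie in [0, 1]")
        object.__setattr__(self, "proportions", props)
        object.__setattr__(self, "words", tuple(self.words))
        object.__setattr__(self, "word_classes", tuple(self.word_classes))
        object.__setattr__(self, "months", tuple(int(m) for m in self.months))

    def row(self, word: str) -> np.ndarray:
        return self.proportions[self.words.index(word)]


def draw_acquisition_age(params: LearningParams, rng: np.random.Generator, size=None):
    """Draw acquisition ages from the accumulator process.

    The age of the threshold-th event under cumulative intensity
    ``delta * t**D`` is ``(G / delta)**(1/D)`` where ``G`` is gamma
    distributed with shape ``accumulation`` and unit scale.
    """
    if not isinstance(params, LearningParams):
        raise TypeError("draw_acquisition_age requires LearningParams")
    g = rng.gamma(shape=params.accumulation, scale=1.0, size=size)
    return (g / params.base_rate) ** (1.0 / params.rate_exponent)


def draw_aoa(kind: ModelKind, params: Params, rng: np.random.Generator, size=None):
    """Draw acquisition ages from any of the four model kinds."""
    if ModelKind(kind) is ModelKind.LOGISTIC:
        return rng.logistic(
            loc=params.intercept / params.slope, scale=1.0 / params.slope, size=size
        )
    return draw_acquisition_age(params, rng, size=size)


def proportions_from_ages(ages: np.ndarray, months) -> np.ndarray:
    """Cumulative fraction of ages at or below each month boundary."""
    ages = np.asarray(ages, dtype=float)
    months = np.asarray(months, dtype=float)
    return (ages[:, None] <= months[None, :]).mean(axis=0)


def simulate_norms(specs: list[SyntheticWordSpec], pop: PopulationSpec) -> NormsTable:
    """Simulate a norms table for ``specs`` under cohort ``pop``.

    Each child's acquisition age is drawn once and thresholded at every
    month, so a word's monthly proportions are non-decreasing and dependent
    across months exactly as in a real cohort.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(pop.seed)
    rows = np.empty((len(specs), len(pop.months)))
    for i, spec in enumerate(specs):
        ages = draw_aoa(spec.kind, spec.params, rng, size=pop.n_children)
        rows[i] = proportions_from_ages(ages, pop.months)
    return NormsTable(
        words=tuple(s.word for s in specs),
        word_classes=tuple(s.word_class for s in specs),
        months=pop.months,
        proportions=rows,
        n_children=pop.n_children,
    )


def solve_base_rate_for_mean(accumulation: float, rate_exponent: float, mean: float) -> float:
    """Base rate giving the accumulator model the requested mean age.

    Inverts ``mean = delta**(-1/D) * Gamma(N + 1/D) / Gamma(N)`` for delta.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    n, d = accumulation, rate_exponent
    log_g = special.gammaln(n + 1.0 / d) - special.gammaln(n)
    return float(np.exp(d * (log_g - np.log(mean))))


def _draw_word_params(
    kind: ModelKind, word_class: str, rng: np.random.Generator, mean_range=(16.0, 40.0)
) -> Params:
    """Sample ground-truth parameters for one fixture word.

    Accumulator parameters live near a negatively sloped line in
    (log10 accumulation, log10 rate_exponent) space — log10 D ~ 0.5 - log10 N
    plus Gaussian noise — so the two are strongly anti-correlated, and the
    base rate is solved so each word's mean age falls in ``mean_range``.
    """
    mean = rng.uniform(*mean_range)
    if kind is ModelKind.LOGISTIC:
        slope = rng.uniform(0.4, 1.2)
        return LogisticParams(slope=slope, intercept=slope * mean)
    if kind is ModelKind.GAMMA:
        # the line crosses rate_exponent == 1 at log10 N = 0.5
        log_n = rng.normal(0.5, 0.2)
        n, d = 10.0**log_n, 1.0
    elif kind is ModelKind.WEIBULL:
        n = 1.0
        d = 10.0 ** rng.normal(0.5, 0.2)
    else:
        log_n = rng.uniform(0.0, 3.0)
        log_d = 0.5 - log_n + rng.normal(0.0, 0.1)
        n, d = 10.0**log_n, 10.0**log_d
    delta = solve_base_rate_for_mean(n, d, mean)
    return LearningParams(accumulation=n, rate_exponent=d, base_rate=delta)


def make_mcdi_fixture(
    seed: int,
    n_children: int = 1000,
    months: tuple[int, ...] = DEFAULT_MONTHS,
    kind_mixture: dict[str, dict[ModelKind, float]] | None = None,
    class_sizes: dict[str, int] | None = None,
) -> tuple[NormsTable, list[SyntheticWordSpec]]:
    """Generate a synthetic 654-word norms table with known ground truth.

    Emulates the structure of the checklist norms: 389 nouns, 102 verbs,
    63 adjectives and 98 closed-class words, each with 15 monthly
    proportions over an effective cohort of ``n_children``.  Returns the
    simulated table together with the per-word generating specs.
    """
    mixture = kind_mixture or DEFAULT_KIND_MIXTURE
    sizes = class_sizes or CLASS_SIZES
    rng = np.random.default_rng(seed)
    specs: list[SyntheticWordSpec] = []
    for word_class in (*WORD_CLASSES, "other"):
        if word_class not in sizes:
            continue
        kinds = list(mixture[word_class].keys())
        weights = np.array([mixture[word_class][k] for k in kinds], dtype=float)
        weights = weights / weights.sum()
        for i in range(sizes[word_class]):
            kind = kinds[rng.choice(len(kinds), p=weights)]
            params = _draw_word_params(kind, word_class, rng)
            specs.append(
                SyntheticWordSpec(
                    word=f"{word_class}_{i:03d}", word_class=word_class, kind=kind, params=params
                )
            )
    pop = PopulationSpec(n_children=n_children, months=tuple(months), seed=seed + 1)
    return simulate_norms(specs, pop), specs


def true_mean_aoa(spec: SyntheticWordSpec) -> float:
    """Closed-form mean age of the generating model of a fixture word."""
    return aoa_mean(spec.kind, spec.params)


#: well-separated shape settings used by the model-selection benchmark; the
#: base rate / intercept is solved per word so mean ages vary.
BENCHMARK_SHAPES: dict[ModelKind, dict[str, float]] = {
    ModelKind.GAMMA: {"accumulation": 8.0, "rate_exponent": 1.0},
    ModelKind.WEIBULL: {"accumulation": 1.0, "rate_exponent": 5.0},
    ModelKind.WEIBULL_GAMMA: {"accumulation": 5.0, "rate_exponent": 3.0},
    ModelKind.LOGISTIC: {"slope": 0.5},
}


def make_selection_benchmark(
    seed: int,
    words_per_kind: int = 50,
    n_children: int = 1000,
    months: tuple[int, ...] = DEFAULT_MONTHS,
    mean_range: tuple[float, float] = (20.0, 26.0),
) -> tuple[NormsTable, list[SyntheticWordSpec]]:
    """Synthetic benchmark with known, well-separated generating kinds.

    Emits ``words_per_kind`` words per model family, each with a mean age
    drawn uniformly from ``mean_range`` and shape parameters fixed at
    ``BENCHMARK_SHAPES`` so the families are identifiable on the observed
    month window.
    """
    rng = np.random.default_rng(seed)
    specs: list[SyntheticWordSpec] = []
    for kind in (ModelKind.GAMMA, ModelKind.WEIBULL, ModelKind.WEIBULL_GAMMA, ModelKind.LOGISTIC):
        shape = BENCHMARK_SHAPES[kind]
        for i in range(words_per_kind):
            mean = rng.uniform(*mean_range)
            if kind is ModelKind.LOGISTIC:
                params: Params = LogisticParams(shape["slope"], shape["slope"] * mean)
            else:
                n, d = shape["accumulation"], shape["rate_exponent"]
                params = LearningParams(n, d, solve_base_rate_for_mean(n, d, mean))
            specs.append(
                SyntheticWordSpec(
                    word=f"{kind.value}_{i:03d}", word_class="other", kind=kind, params=params
                )
            )
    pop = PopulationSpec(n_children=n_children, months=tuple(months), seed=seed + 1)
    return simulate_norms(specs, pop), specs
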