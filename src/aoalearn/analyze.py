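"""Downstream analyses of fitted word-learning parameters.

Median age of acquisition, best-model contingency tables with chi-square
independence tests, parameter-attribute correlations with Fisher-z
confidence intervals, and moving-average developmental trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelKind, aoa_mean
from .fit import WordFit

__all__ = [
    "CENSORED_MEDIAN",
    "SelectionSummary",
    "TrendSeries",
    "CorrelationResult",
    "median_aoa",
    "crosstab_selection",
    "chi_square_independence",
    "fisher_ci",
    "correlate_with_attributes",
    "moving_average_trend",
    "estimated_mean_aoa",
]

#: sentinel month for words never reaching 50% inside the observed window
CENSORED_MEDIAN = 31

KIND_ORDER = [k.value for k in (ModelKind.GAMMA, ModelKind.WEIBULL, ModelKind.WEIBULL_GAMMA, ModelKind.LOGISTIC)]


@dataclass(frozen=True)
class SelectionSummary:
    """Best-model counts cross-tabulated over word groups."""

    counts: pd.DataFrame  # index: group label, columns: model kind

    @property
    def proportions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.where(totals > 0, 1.0), axis=0)

    @property
    def n_words(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class TrendSeries:
    """Moving-averaged parameter values ordered by estimated mean AoA."""

    word_class: str
    param: str
    words: tuple[str, ...]
    mean_aoa: np.ndarray
    values: np.ndarray
    smoothed: np.ndarray
    window_before: int = 9
    window_after: int = 10


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int


def median_aoa(p, months, censored: int = CENSORED_MEDIAN) -> int:
    """First month at which the acquisition proportion reaches 50%.

    Words never reaching 50% in the window get the sentinel ``censored``
    (default 31, i.e. "later than the observed range").
    """
    p = np.asarray(p, dtype=float)
    months = np.asarray(months)
    if p.size == 0:
        raise ValueError("empty proportion row")
    if p.shape != months.shape:
        raise ValueError("proportions and months must align")
    hit = np.nonzero(p >= 0.5)[0]
    if hit.size == 0:
        return int(censored)
    return int(months[hit[0]])


def crosstab_selection(
    winners: pd.DataFrame,
    group_col: str = "group",
    kind_col: str = "kind",
    groups: list | None = None,
    valid_groups: list | None = None,
) -> SelectionSummary:
    """Cross-tabulate winning model kinds over a grouping column.

    ``winners`` needs one row per word with a group label and the winning
    kind.  ``groups`` fixes the row order and retains empty groups as zero
    rows; ``valid_groups`` rejects unknown labels.
    """
    if group_col not in winners or kind_col not in winners:
        raise ValueError(f"winners frame must have columns {group_col!r} and {kind_col!r}")
    labels = winners[group_col]
    if valid_groups is not None:
        unknown = sorted(set(labels) - set(valid_groups))
        if unknown:
            raise ValueError(f"unknown group label(s): {unknown}")
    kinds = winners[kind_col].map(lambda k: ModelKind(k).value)
    table = pd.crosstab(labels, kinds)
    row_order = groups if groups is not None else sorted(table.index)
    table = table.reindex(index=row_order, columns=KIND_ORDER, fill_value=0).astype(int)
    table.index.name = group_col
    table.columns.name = kind_col
    return SelectionSummary(counts=table)


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Expected counts come from the row/column margins; returns
    ``(statistic, df, p_value)``.  A zero row or column margin is an error
    naming the offending line.
    """
    obs = np.asarray(table, dtype=float)
    if isinstance(table, pd.DataFrame):
        row_names, col_names = list(table.index), list(table.columns)
    else:
        row_names = list(range(obs.shape[0]))
        col_names = list(range(obs.shape[1]))
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("contingency counts must be non-negative")
    row_sum = obs.sum(axis=1)
    col_sum = obs.sum(axis=0)
    for i, s in enumerate(row_sum):
        if s == 0:
            raise ValueError(f"row {row_names[i]!r} has a zero margin")
    for j, s in enumerate(col_sum):
        if s == 0:
            raise ValueError(f"column {col_names[j]!r} has a zero margin")
    expected = np.outer(row_sum, col_sum) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p_value = float(stats.chi2.sf(statistic, df))
    return statistic, df, p_value


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a Pearson correlation via the Fisher z transform."""
    if n < 4:
        raise ValueError("need at least 4 observations for a Fisher interval")
    if not (-1.0 < r < 1.0):
        raise ValueError("r must lie strictly inside (-1, 1)")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - zq * se)), float(np.tanh(z + zq * se))


def correlate_with_attributes(
    fits: pd.DataFrame,
    attributes: pd.DataFrame,
    param: str,
    attribute: str | None = None,
    log_transform: bool = False,
    log_attribute: bool = False,
) -> CorrelationResult:
    """Pearson correlation of a fitted parameter with a word attribute.

    ``fits`` needs columns ``word`` and ``param``; ``attributes`` is a long
    table with columns ``word``, ``attribute``, ``value`` (``attribute``
    optional when the table carries a single ``value`` column).  Only words
    present in both tables are analyzed (inner join).  ``log_transform``
    applies a natural log to the parameter, ``log_attribute`` to the
    attribute values.
    """
    if param not in fits.columns:
        raise ValueError(f"fits frame has no column {param!r}")
    attrs = attributes
    if attribute is not None:
        if "attribute" not in attrs.columns:
            raise ValueError("attributes frame has no 'attribute' column to filter on")
        attrs = attrs[attrs["attribute"] == attribute]
    merged = fits[["word", param]].merge(attrs[["word", "value"]], on="word", how="inner")
    merged = merged.dropna()
    n = len(merged)
    if n < 4:
        raise ValueError(f"need at least 4 shared words, got {n}")
    x = merged[param].to_numpy(dtype=float)
    y = merged["value"].to_numpy(dtype=float)
    if log_transform:
        x = np.log(x)
    if log_attribute:
        y = np.log(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return CorrelationResult(r=r, ci_low=r, ci_high=r, n=n)
    lo, hi = fisher_ci(r, n)
    return CorrelationResult(r=r, ci_low=lo, ci_high=hi, n=n)


def estimated_mean_aoa(fit: WordFit) -> float:
    """Model-implied mean acquisition age of a fitted word (months).

    Delegates to the closed-form mean; for a logistic winner this is
    intercept/slope.  May exceed the observed window — no clipping.
    """
    return aoa_mean(fit.kind, fit.params)


def moving_average_trend(
    fits: pd.DataFrame,
    param: str,
    word_class: str | None = None,
    order_col: str = "mean_aoa",
    window_before: int = 9,
    window_after: int = 10,
) -> TrendSeries:
    """Moving average of a parameter over words ranked by mean AoA.

    Words are sorted by ``order_col`` (model-implied mean age); the value at
    rank t is the mean of ranks t-window_before .. t+window_after, with the
    window truncated at the sequence boundaries so every word gets a value.
    """
    needed = {"word", param, order_col}
    missing = needed - set(fits.columns)
    if missing:
        raise ValueError(f"fits frame missing column(s) {sorted(missing)}")
    if len(fits) == 0:
        raise ValueError("need at least one word")
    ordered = fits.sort_values(order_col, kind="stable").reset_index(drop=True)
    values = ordered[param].to_numpy(dtype=float)
    n = len(values)
    smoothed = np.empty(n)
    for t in range(n):
        lo = max(0, t - window_before)
        hi = min(n, t + window_after + 1)
        smoothed[t] = values[lo:hi].mean()
    return TrendSeries(
        word_class=word_class or "all",
        param=param,
        words=tuple(ordered["word"]),
        mean_aoa=ordered[order_col].to_numpy(dtype=float),
        values=values,
        smoothed=smoothed,
        window_before=window_before,
        window_after=window_after,
    )
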