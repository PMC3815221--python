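"""Optional matplotlib views of selection summaries and parameter trends."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .analyze import SelectionSummary, TrendSeries

__all__ = ["plot_selection_proportions", "plot_trend"]


def plot_selection_proportions(summary: SelectionSummary, path, title: str = "") -> None:
    """Stacked-bar view of best-model shares per group (class or age bin)."""
    props = summary.proportions
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(props)), 4))
    bottom = None
    for kind in props.columns:
        ax.bar(props.index.astype(str), props[kind], bottom=bottom, label=kind)
        bottom = props[kind] if bottom is None else bottom + props[kind]
    ax.set_ylabel("proportion of words")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trend(series: TrendSeries, path) -> None:
    """Scatter of a parameter against mean AoA with its moving average."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(series.mean_aoa, series.values, s=8, alpha=0.4, label="words")
    ax.plot(series.mean_aoa, series.smoothed, color="C3", label="moving average")
    ax.set_yscale("log")
    ax.set_xlabel("estimated mean AoA (months)")
    ax.set_ylabel(series.param)
    ax.set_title(f"{series.word_class}: {series.param} trend")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
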