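"""CSV input/output with provenance headers.

All tables are plain UTF-8 CSV.  Norms tables carry columns
``word, class, p16..p30``; fit tables carry per-word per-model parameter
columns.  Every file written here starts with comment lines recording the
package version, the seed and a hash of the run configuration, so a run can
be reproduced from its outputs alone.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .models import LearningParams, LogisticParams, ModelKind
from .fit import WordFit
from .simulate import DEFAULT_MONTHS, NormsTable, SyntheticWordSpec

__all__ = [
    "config_hash",
    "provenance_header",
    "read_norms",
    "write_norms",
    "write_word_specs",
    "read_word_specs",
    "write_fits",
    "read_fits",
]

logger = logging.getLogger(__name__)

VALID_CLASSES = ("noun", "verb", "adjective", "closed", "other")


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: int | None = None, config: dict | None = None) -> str:
    lines = [f"# aoalearn {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config_sha256={config_hash(config)}")
    return "\n".join(lines) + "\n"


def _write_csv(df: pd.DataFrame, path, seed=None, config=None) -> None:
    buf = _io.StringIO()
    buf.write(provenance_header(seed=seed, config=config))
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _month_cols(months) -> list[str]:
    return [f"p{int(m)}" for m in months]


def write_norms(table: NormsTable, path, seed: int | None = None, config: dict | None = None) -> None:
    df = pd.DataFrame({"word": table.words, "class": table.word_classes})
    for j, col in enumerate(_month_cols(table.months)):
        df[col] = table.proportions[:, j]
    _write_csv(df, path, seed=seed, config=config)


def read_norms(path, months=DEFAULT_MONTHS, n_children: int = 1000) -> NormsTable:
    """Read and validate a norms CSV.

    Missing columns, duplicate words and out-of-range proportions are
    rejected with the offending row named; non-monotone rows are accepted
    with a warning (parent-report norms can be noisy).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    cols = _month_cols(months)
    missing = [c for c in ["word", "class", *cols] if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    dupes = df["word"][df["word"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path.name}: duplicate word key(s) {sorted(set(dupes))}")
    props = np.empty((len(df), len(cols)))
    for j, col in enumerate(cols):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()]
        if len(bad):
            raise ValueError(
                f"{path.name}: column {col} row {bad[0] + 2}: "
                f"unparseable value {df[col].iloc[bad[0]]!r}"
            )
        out_of_range = df.index[(values < 0) | (values > 1)]
        if len(out_of_range):
            i = out_of_range[0]
            raise ValueError(
                f"{path.name}: column {col} row {i + 2}: value {values.iloc[i]} outside [0, 1]"
            )
        props[:, j] = values.to_numpy()
    non_monotone = np.any(np.diff(props, axis=1) < 0, axis=1)
    for word in df["word"][non_monotone]:
        logger.warning("norms row for %r is non-monotone across months", word)
    return NormsTable(
        words=tuple(df["word"].astype(str)),
        word_classes=tuple(df["class"].astype(str)),
        months=tuple(months),
        proportions=props,
        n_children=n_children,
    )


def write_word_specs(
    specs: list[SyntheticWordSpec], path, seed: int | None = None, config: dict | None = None
) -> None:
    """Serialize ground-truth word specs as CSV (columns word,class,kind,N,D,delta,slope,intercept)."""
    rows = []
    for s in specs:
        row = {
            "word": s.word,
            "class": s.word_class,
            "kind": s.kind.value,
            "N": np.nan,
            "D": np.nan,
            "delta": np.nan,
            "slope": np.nan,
            "intercept": np.nan,
        }
        if isinstance(s.params, LearningParams):
            row.update(N=s.params.accumulation, D=s.params.rate_exponent, delta=s.params.base_rate)
        else:
            row.update(slope=s.params.slope, intercept=s.params.intercept)
        rows.append(row)
    _write_csv(pd.DataFrame(rows), path, seed=seed, config=config)


def read_word_specs(path) -> list[SyntheticWordSpec]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    specs = []
    for _, row in df.iterrows():
        kind = ModelKind(row["kind"])
        if kind is ModelKind.LOGISTIC:
            params = LogisticParams(slope=float(row["slope"]), intercept=float(row["intercept"]))
        else:
            params = LearningParams(
                accumulation=float(row["N"]),
                rate_exponent=float(row["D"]),
                base_rate=float(row["delta"]),
            )
        specs.append(
            SyntheticWordSpec(
                word=str(row["word"]), word_class=str(row["class"]), kind=kind, params=params
            )
        )
    return specs


def fits_to_frame(
    fits: list[WordFit],
    word_classes: dict[str, str] | None = None,
    winners: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Flatten fit results to a table, one row per (word, model)."""
    rows = []
    for f in fits:
        row = {
            "word": f.word,
            "class": (word_classes or {}).get(f.word, ""),
            "kind": f.kind.value,
            "N": np.nan,
            "D": np.nan,
            "delta": np.nan,
            "slope": np.nan,
            "intercept": np.nan,
            "loglik": f.loglik,
            "bic": f.bic,
            "converged": f.converged,
            "winner_flag": bool(winners and (f.word, f.kind.value) in winners),
        }
        if isinstance(f.params, LearningParams):
            row.update(N=f.params.accumulation, D=f.params.rate_exponent, delta=f.params.base_rate)
        else:
            row.update(slope=f.params.slope, intercept=f.params.intercept)
        rows.append(row)
    return pd.DataFrame(rows)


def write_fits(df: pd.DataFrame, path, seed: int | None = None, config: dict | None = None) -> None:
    _write_csv(df, path, seed=seed, config=config)


def read_fits(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"word", "kind", "loglik", "bic"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fits table missing column(s) {sorted(missing)}")
    return df
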