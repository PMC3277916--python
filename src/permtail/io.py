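"""Readers and writers for permutation-value tables and result files.

Input tables are delimited text with one column per tested event: an
optional single header row, the test statistic on the first data row, and
the permutation values below it.  Files with a ``.csv`` extension are
comma-separated; everything else is read as tab-separated.  Non-numeric,
NaN and Inf cells are ignored per column, so columns may carry different
numbers of permutation values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimator import PermutationColumn

__all__ = [
    "FormatError",
    "PermutationTable",
    "ColumnValidation",
    "read_table",
    "write_table",
    "validate_for_tail",
    "write_results",
    "plot_results",
    "results_figure",
    "results_frame",
]

#: minimum permutation values per column for the GPD tail path
MIN_TAIL_VALUES = 1000

_RESULT_FMT = "{:.12e}"


class FormatError(ValueError):
    """The input file does not follow the permutation-value table layout."""


@dataclass(frozen=True)
class PermutationTable:
    columns: tuple[PermutationColumn, ...]
    has_header: bool

    def __post_init__(self) -> None:
        if self.has_header:
            labels = [c.label for c in self.columns]
            if len(set(labels)) != len(labels):
                raise FormatError("column labels must be unique when a header row is present")

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class ColumnValidation:
    label: str | None
    n_values: int
    tail_eligible: bool


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except (TypeError, ValueError):
        return False


def _resolve_sep(path, dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect == "auto":
        name = getattr(path, "name", path)
        suffix = Path(str(name)).suffix.lower()
        return "," if suffix == ".csv" else "\t"
    raise ValueError(f"unknown dialect {dialect!r}; choose auto, tsv or csv")


def read_table(path, dialect: str = "auto") -> PermutationTable:
    """Parse a permutation-value table from a file path or text stream.

    A header is detected when the first row contains any cell that does
    not parse as a number.  The first data row holds the test statistics;
    all numeric, finite cells below it are the permutation values.
    """
    sep = _resolve_sep(path, dialect)
    raw = pd.read_csv(
        path, sep=sep, header=None, dtype=str, skip_blank_lines=True,
        keep_default_na=False, engine="python",
    )
    if raw.empty:
        raise FormatError("empty input table")
    raw = raw.apply(lambda s: s.str.strip())

    first = raw.iloc[0]
    has_header = any(cell != "" and not _is_number(cell) for cell in first)
    labels = [str(c) if str(c) != "" else None for c in first] if has_header else [None] * raw.shape[1]
    body = raw.iloc[1:] if has_header else raw
    if body.empty:
        raise FormatError("no numeric data row: the table holds no test statistics")

    stats_row = body.iloc[0]
    value_rows = body.iloc[1:]
    columns = []
    for j in range(raw.shape[1]):
        name = labels[j] or f"column {j + 1}"
        x0 = pd.to_numeric(pd.Series([stats_row.iloc[j]]), errors="coerce").iloc[0]
        if not np.isfinite(x0):
            raise FormatError(f"{name}: test statistic {stats_row.iloc[j]!r} is not a finite number")
        vals = pd.to_numeric(value_rows.iloc[:, j], errors="coerce").to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise FormatError(f"{name}: a test statistic but no permutation values")
        columns.append(PermutationColumn(x0=float(x0), values=vals, label=labels[j]))
    return PermutationTable(columns=tuple(columns), has_header=has_header)


def write_table(table: PermutationTable, path, dialect: str = "auto") -> None:
    """Serialize a table in the same layout ``read_table`` expects."""
    sep = _resolve_sep(path, dialect)
    depth = max(c.n for c in table.columns)
    rows = []
    if table.has_header:
        rows.append([c.label or "" for c in table.columns])
    rows.append([repr(float(c.x0)) for c in table.columns])
    for i in range(depth):
        rows.append([repr(float(c.values[i])) if i < c.n else "" for c in table.columns])
    text = "\n".join(sep.join(row) for row in rows) + "\n"
    Path(path).write_text(text)


def validate_for_tail(table: PermutationTable) -> list[ColumnValidation]:
    """Per-column check of the >= 1000 permutation-value rule.

    Ineligible columns may still receive an empirical estimate; the tail
    path is disallowed for them.
    """
    return [
        ColumnValidation(label=c.label, n_values=c.n, tail_eligible=c.n >= MIN_TAIL_VALUES)
        for c in table.columns
    ]


def _fmt(value: float | None) -> str:
    if value is None or not math.isfinite(value):
        return "NA"
    return _RESULT_FMT.format(value)


def write_results(
    results,
    path,
    with_ci: bool = True,
    with_convergence: bool = False,
) -> None:
    """Write the estimate table: optional label header, a row of P-value
    estimates, then (optionally) CI lower and upper rows and a final row
    of 1/0 convergence flags.  Failed estimates appear as NA."""
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    rows = []
    if any(r.label is not None for r in results):
        rows.append([r.label or "" for r in results])
    rows.append([_fmt(r.p_value) for r in results])
    if with_ci:
        rows.append([_fmt(r.ci_lower) for r in results])
        rows.append([_fmt(r.ci_upper) for r in results])
    if with_convergence:
        rows.append(
            ["NA" if r.converged is None else str(int(bool(r.converged))) for r in results]
        )
    Path(path).write_text("\n".join("\t".join(row) for row in rows) + "\n")


def results_figure(results):
    """Build the summary figure: per-column -log10 P with CI whiskers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = list(results)
    if not results:
        raise ValueError("no results to plot")

    def neglog(p):
        if p is None or not math.isfinite(p) or p <= 0:
            return math.nan
        return -math.log10(p)

    x = np.arange(1, len(results) + 1)
    y = np.array([neglog(r.p_value) for r in results])
    lo = np.array([neglog(r.ci_upper) for r in results])  # upper p -> lower bar
    hi = np.array([neglog(r.ci_lower) for r in results])

    fig, ax = plt.subplots(figsize=(max(4.0, 0.6 * len(results) + 2), 4.0))
    have_ci = np.isfinite(lo) & np.isfinite(hi) & np.isfinite(y)
    yerr = np.zeros((2, len(results)))
    yerr[0, have_ci] = (y - lo)[have_ci]
    yerr[1, have_ci] = (hi - y)[have_ci]
    ax.errorbar(
        x, y, yerr=np.where(np.isfinite(yerr), yerr, 0.0),
        fmt="o", capsize=3, color="tab:blue", ecolor="tab:gray",
    )
    ax.set_xticks(x)
    ax.set_xticklabels([r.label or str(i) for i, r in enumerate(results, 1)], rotation=45, ha="right")
    ax.set_ylabel(r"$-\log_{10}\,\hat{P}$")
    ax.set_xlabel("tested event")
    fig.tight_layout()
    return fig


def plot_results(results, path) -> None:
    """Write the summary plot as a raster image (PNG)."""
    import matplotlib.pyplot as plt

    fig = results_figure(results)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def results_frame(results) -> pd.DataFrame:
    """Convenience DataFrame view of a sequence of EstimateResult."""
    results = list(results)
    return pd.DataFrame(
        {
            "label": [r.label for r in results],
            "p_value": [r.p_value for r in results],
            "estimator": [r.estimator for r in results],
            "ci_lower": [r.ci_lower for r in results],
            "ci_upper": [r.ci_upper for r in results],
            "converged": [r.converged for r in results],
        }
    )
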