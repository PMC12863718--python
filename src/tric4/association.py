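"""Labeled contingency tables and Pearson chi-squared association.

The table type is shared by the haplotype cross-tabulation stage and the
copy-number association stage.  The chi-squared statistic is computed
directly from the observed/expected decomposition (no continuity
correction); all-zero rows and columns are dropped before testing and the
degrees of freedom are computed on the retained dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, LabelError, NoDataError

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "build_gcn_table",
    "pearson_chisq",
    "summarize_fractions",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An R x C cross-tabulation with row and column labels."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"counts shape {counts.shape} does not match labels "
                f"({len(self.row_labels)} x {len(self.col_labels)})"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(str(r) for r in self.row_labels))
        object.__setattr__(self, "col_labels", tuple(str(c) for c in self.col_labels))

    # -- construction -------------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        row_labels: Sequence[str] | None = None,
        col_labels: Sequence[str] | None = None,
    ) -> "ContingencyTable":
        """Cross-tabulate (row_key, col_key) observations.

        Unless explicit label orders are given, labels appear in first-seen
        order.  Labels listed but never observed yield all-zero rows/columns.
        """
        pairs = list(pairs)
        rows = list(row_labels) if row_labels is not None else []
        cols = list(col_labels) if col_labels is not None else []
        for r, c in pairs:
            if row_labels is None and r not in rows:
                rows.append(r)
            if col_labels is None and c not in cols:
                cols.append(c)
        counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
        ri = {r: i for i, r in enumerate(rows)}
        ci = {c: i for i, c in enumerate(cols)}
        for r, c in pairs:
            if r not in ri or c not in ci:
                raise LabelError(f"observation ({r!r}, {c!r}) outside fixed labels")
            counts[ri[r], ci[c]] += 1
        return cls(tuple(rows), tuple(cols), counts)

    # -- accessors ----------------------------------------------------------

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def row(self, label: str) -> np.ndarray:
        try:
            return self.counts[self.row_labels.index(label)]
        except ValueError:
            raise LabelError(f"unknown row label {label!r}") from None

    def col(self, label: str) -> np.ndarray:
        try:
            return self.counts[:, self.col_labels.index(label)]
        except ValueError:
            raise LabelError(f"unknown column label {label!r}") from None

    # -- serialization ------------------------------------------------------

    def to_frame(self, margins: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.row_labels),
                          columns=list(self.col_labels))
        if margins:
            df["All"] = df.sum(axis=1)
            df.loc["All"] = df.sum(axis=0)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame(margins=True).to_csv(path, sep="\t", index_label="")

    @classmethod
    def from_tsv(cls, path) -> "ContingencyTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        if "All" in df.columns:
            df = df.drop(columns="All")
        if "All" in df.index:
            df = df.drop(index="All")
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy())


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-squared test result on a contingency table."""

    statistic: float
    df: int
    p_value: float
    warnings: tuple[str, ...] = field(default=())

    def formatted_p(self) -> str:
        """Scientific-notation display with 3 significant digits."""
        return f"{self.p_value:.2E}"


def build_gcn_table(
    calls: Sequence[tuple[int, int]],
    paralog: str | None = None,
) -> ContingencyTable:
    """Cross-tabulate per-sample gene copy number against 101-dosage.

    ``calls`` holds (gcn, trisnp_101_dosage) pairs; rows are the observed
    copy-number values in ascending order, columns the dosages 0, 1, 2.
    ``paralog`` is carried only for provenance in CLI output.
    """
    calls = list(calls)
    if not calls:
        raise NoDataError("no copy-number calls supplied")
    for gcn, dose in calls:
        if dose not in (0, 1, 2):
            raise ValueError(f"dosage must be in {{0,1,2}}, got {dose}")
    gcns = sorted({g for g, _ in calls})
    return ContingencyTable.from_pairs(
        ((str(g), str(d)) for g, d in calls),
        row_labels=[str(g) for g in gcns],
        col_labels=["0", "1", "2"],
    )


def _retained(table: ContingencyTable) -> np.ndarray:
    counts = table.counts
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    return counts[np.ix_(keep_r, keep_c)]


def pearson_chisq(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-squared test of independence on the full R x C table.

    Expected counts come from the row/column margins; df = (r-1)(c-1) on
    the retained (non-all-zero) dimensions; the p-value is the upper tail
    of the chi-square distribution.  No continuity correction is applied.
    Cells with expected count < 5 raise a warning flag rather than an
    error.
    """
    if table.grand_total <= 0:
        raise DegenerateTableError("table has zero grand total")
    obs = _retained(table).astype(float)
    r, c = obs.shape
    if r < 2 or c < 2:
        raise DegenerateTableError(
            f"need >= 2 informative rows and columns, got {r} x {c}"
        )
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    p_value = float(stats.chi2.sf(statistic, df))
    flags: list[str] = []
    n_small = int((expected < 5).sum())
    if n_small:
        flags.append(f"{n_small} cells with expected count < 5")
    return ChiSquareResult(statistic, df, max(p_value, np.nextafter(0, 1)),
                           tuple(flags))


def summarize_fractions(
    table: ContingencyTable,
    row: str | None = None,
    col: str | None = None,
) -> tuple[int, int, float]:
    """Exact (numerator, denominator, fraction) for a row, column or cell.

    With both ``row`` and ``col`` the numerator is a single cell; with one
    of them, a margin total; with neither, the full table (N/N = 1.0).
    The denominator is always the grand total.
    """
    denom = table.grand_total
    if denom == 0:
        raise NoDataError("empty table")
    if row is not None and col is not None:
        num = int(table.row(row)[table.col_labels.index(col)]) \
            if col in table.col_labels else _raise_label(col)
    elif row is not None:
        num = int(table.row(row).sum())
    elif col is not None:
        num = int(table.col(col).sum())
    else:
        num = denom
    return num, denom, num / denom


def _raise_label(label: str):
    raise LabelError(f"unknown column label {label!r}")
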