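"""Long-format longitudinal tables: ingest, validation, filtering, grouping.

Every test in this package consumes the same structure: one row per
observation, with a subject identifier, a numeric independent axis
(usually time), a numeric response, and zero or more categorical
metadata columns. Internally the table is a pandas DataFrame with
canonical column names ``subject``, ``x``, ``y`` plus the category
columns; the original column names are remembered for labeling output.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyAfterFilterError,
    EmptyInputError,
    InconsistentGroupingError,
    SchemaError,
)

SUBJECT = "subject"
X = "x"
Y = "y"


@dataclass(frozen=True)
class LoadReport:
    """What happened while reading a file: rows seen, rows dropped and why."""

    n_rows_read: int
    n_rows_dropped: int
    dropped_reasons: Mapping[str, int] = field(default_factory=dict)


class LongitudinalTable:
    """Validated long-format observations.

    Parameters
    ----------
    df : DataFrame with columns ``subject``, ``x``, ``y`` and one column
        per category. ``x`` and ``y`` must be finite floats; ``subject``
        non-missing. Rows need not be sorted and a subject may repeat an
        ``x`` value (technical replicates are legal).
    category_cols : names of the categorical metadata columns in ``df``.
    column_names : optional mapping canonical -> original column name,
        used for axis labels in plots and CLI output.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        category_cols: Sequence[str] = (),
        column_names: Mapping[str, str] | None = None,
        load_report: LoadReport | None = None,
    ):
        category_cols = list(category_cols)
        missing = [c for c in [SUBJECT, X, Y, *category_cols] if c not in df.columns]
        if missing:
            raise SchemaError(f"table is missing columns {missing}")
        df = df.loc[:, [SUBJECT, X, Y, *category_cols]].copy()
        df[SUBJECT] = df[SUBJECT].astype(str).str.strip()
        df[X] = pd.to_numeric(df[X], errors="raise").astype(float)
        df[Y] = pd.to_numeric(df[Y], errors="raise").astype(float)
        for c in category_cols:
            df[c] = df[c].astype(str).str.strip()
        if len(df) == 0:
            raise EmptyInputError("table has no rows")
        if df[SUBJECT].isin(["", "nan", "None"]).any() or df[SUBJECT].isna().any():
            raise EmptyInputError("table contains rows with a missing subject id")
        if not np.isfinite(df[X].to_numpy()).all() or not np.isfinite(df[Y].to_numpy()).all():
            raise EmptyInputError("table contains non-finite x or y values")
        df = df.reset_index(drop=True)
        self._df = df
        self.category_cols = category_cols
        self.column_names = dict(column_names or {})
        self.load_report = load_report

    # -- basic accessors -------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def n_rows(self) -> int:
        return len(self._df)

    @property
    def subjects(self) -> list[str]:
        return list(pd.unique(self._df[SUBJECT]))

    @property
    def n_subjects(self) -> int:
        return self._df[SUBJECT].nunique()

    @property
    def x(self) -> np.ndarray:
        return self._df[X].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self._df[Y].to_numpy()

    def subject_rows(self) -> dict[str, np.ndarray]:
        """Row indices (positional) of each subject's observations."""
        return {
            str(s): np.asarray(idx)
            for s, idx in self._df.groupby(SUBJECT, sort=False).indices.items()
        }

    def with_y(self, y_new: np.ndarray) -> "LongitudinalTable":
        df = self._df.copy()
        df[Y] = np.asarray(y_new, dtype=float)
        return LongitudinalTable(df, self.category_cols, self.column_names)

    def subset_rows(self, mask_or_index) -> "LongitudinalTable":
        return LongitudinalTable(
            self._df.loc[mask_or_index], self.category_cols, self.column_names
        )

    def check_minimum_extent(self) -> None:
        """Require >=2 distinct subjects and >=2 distinct x values overall."""
        if self.n_subjects < 2:
            raise EmptyInputError("need at least 2 distinct subjects")
        if self._df[X].nunique() < 2:
            raise EmptyInputError("need at least 2 distinct x values")

    def __eq__(self, other) -> bool:
        if not isinstance(other, LongitudinalTable):
            return NotImplemented
        return self.category_cols == other.category_cols and self._df.equals(other._df)

    def __repr__(self) -> str:
        return (
            f"LongitudinalTable({self.n_rows} rows, {self.n_subjects} subjects, "
            f"categories={self.category_cols})"
        )

    def write(self, path: str | Path) -> None:
        """Write as tab-delimited text using the original column names."""
        df = self._df.rename(columns=self.column_names)
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GroupPair:
    """The two-group comparison unit produced by :func:`split_groups`."""

    group1_table: LongitudinalTable
    group2_table: LongitudinalTable
    category_name: str
    group1_label: str
    group2_label: str

    def __post_init__(self):
        s1 = set(self.group1_table.subjects)
        s2 = set(self.group2_table.subjects)
        if s1 & s2:
            raise InconsistentGroupingError(
                f"groups share subjects: {sorted(s1 & s2)[:5]}"
            )


class FilterResult(NamedTuple):
    table: LongitudinalTable
    dropped_subjects: tuple[str, ...]


def _sniff_delimiter(header_line: str) -> str:
    try:
        return csv.Sniffer().sniff(header_line, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_long_table(
    path: str | Path,
    subject_col: str,
    x_col: str,
    y_col: str,
    category_cols: Iterable[str] = (),
) -> LongitudinalTable:
    """Read a tab-delimited (or comma-delimited, auto-sniffed) long table.

    Rows with a missing subject, or a non-numeric/non-finite x or y, are
    dropped and counted in the returned table's ``load_report``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        delim = _sniff_delimiter(header)
        fh.seek(0)
        raw = pd.read_csv(io.StringIO(fh.read()), sep=delim, dtype=str)
    category_cols = list(category_cols)
    wanted = [subject_col, x_col, y_col, *category_cols]
    absent = [c for c in wanted if c not in raw.columns]
    if absent:
        raise SchemaError(
            f"columns {absent} not found; available columns: {list(raw.columns)}"
        )
    n_read = len(raw)

    def parse_float(v):
        # python's float() round-trips repr output exactly
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    df = pd.DataFrame(
        {
            SUBJECT: raw[subject_col].astype(str).str.strip(),
            X: raw[x_col].map(parse_float),
            Y: raw[y_col].map(parse_float),
        }
    )
    for c in category_cols:
        df[c] = raw[c].astype(str).str.strip()
    bad_subject = raw[subject_col].isna() | (df[SUBJECT] == "")
    bad_x = ~np.isfinite(df[X].to_numpy(dtype=float, na_value=np.nan))
    bad_y = ~np.isfinite(df[Y].to_numpy(dtype=float, na_value=np.nan))
    keep = ~(bad_subject | bad_x | bad_y)
    report = LoadReport(
        n_rows_read=n_read,
        n_rows_dropped=int((~keep).sum()),
        dropped_reasons={
            "missing_subject": int(bad_subject.sum()),
            "bad_x": int(bad_x.sum()),
            "bad_y": int(bad_y.sum()),
        },
    )
    df = df.loc[keep]
    if len(df) == 0:
        raise EmptyInputError(f"no valid rows in {path} after dropping {n_read} bad rows")
    names = {SUBJECT: subject_col, X: x_col, Y: y_col}
    table = LongitudinalTable(df, category_cols, names, load_report=report)
    table.check_minimum_extent()
    return table


def filter_low_prevalence(table: LongitudinalTable, cut_low: int) -> FilterResult:
    """Keep subjects with strictly more than ``cut_low`` observations.

    ``cut_low=0`` keeps everything; ``cut_low=1`` removes subjects seen
    only once. Raises :class:`EmptyAfterFilterError` if nothing survives.
    """
    if cut_low < 0:
        raise ValueError("cut_low must be non-negative")
    counts = table.df[SUBJECT].value_counts()
    keep = set(counts[counts > cut_low].index)
    dropped = tuple(s for s in table.subjects if s not in keep)
    if not keep:
        raise EmptyAfterFilterError(
            f"cut_low={cut_low} removed all {table.n_subjects} subjects"
        )
    if not dropped:
        return FilterResult(table, ())
    mask = table.df[SUBJECT].isin(keep)
    return FilterResult(table.subset_rows(mask), dropped)


def split_groups(
    table: LongitudinalTable,
    category_name: str,
    group1_label: str,
    group2_label: str,
) -> GroupPair:
    """Split into the two groups to compare; other labels are excluded.

    Each subject must carry a single label across all of its rows.
    """
    if category_name not in table.category_cols:
        raise SchemaError(
            f"category {category_name!r} not in table categories {table.category_cols}"
        )
    df = table.df
    g1, g2 = group1_label.strip(), group2_label.strip()
    for lab in (g1, g2):
        if not (df[category_name] == lab).any():
            raise ValueError(
                f"label {lab!r} does not occur in category {category_name!r}"
            )
    labels_per_subject = df.groupby(SUBJECT, sort=False)[category_name].agg(
        lambda s: set(s)
    )
    for subj, labs in labels_per_subject.items():
        both = labs & {g1, g2}
        if len(both) > 1:
            raise InconsistentGroupingError(
                f"subject {subj!r} carries both labels {sorted(both)}"
            )
    t1 = table.subset_rows(df[category_name] == g1)
    t2 = table.subset_rows(df[category_name] == g2)
    return GroupPair(t1, t2, category_name, g1, g2)
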