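"""Interval-wise two-group comparison on per-subject splines.

Each subject is summarized by its own loess curve (filling gaps in its
time series), every curve is evaluated on a common grid spanning the
union of subject ranges — never extrapolated beyond a subject's own
first and last observation — and at each grid point the two groups'
interpolated values are compared with a two-sample test, provided both
groups contribute at least ``test_density`` subjects there. No
multiplicity adjustment is applied: the output carries every raw
per-interval p-value so callers can adjust as they see fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GroupPair, LongitudinalTable, filter_low_prevalence
from .errors import InsufficientDataError
from .loess import DEFAULT_DEGREE, DEFAULT_SPAN, LoessModel, fit_loess

logger = logging.getLogger(__name__)


@dataclass
class SlidingParams:
    ints: int = 100
    test_density: int = 3
    span: float = DEFAULT_SPAN
    degree: int = DEFAULT_DEGREE
    cut_low: int = 0
    interval_test: str = "mann_whitney"

    def __post_init__(self):
        if self.ints < 2:
            raise ValueError("ints must be >= 2")
        if self.test_density < 2:
            raise ValueError("test_density must be >= 2 (no two-sample test below 2)")
        if self.interval_test not in ("mann_whitney", "welch_t"):
            raise ValueError("interval_test must be 'mann_whitney' or 'welch_t'")


class SubjectCurve:
    """A per-subject curve: loess when possible, else linear interpolation.

    ``kind`` records how the curve was obtained: ``"loess"`` at the
    requested degree, ``"loess_degree1"`` after a degree fallback, or
    ``"linear"`` (straight lines between the subject's own points).
    """

    def __init__(self, x, y, span: float, degree: int):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.unique(x).size < 2:
            raise InsufficientDataError("a curve needs >= 2 distinct x values")
        self.x_min = float(x.min())
        self.x_max = float(x.max())
        self._model: LoessModel | None = None
        self.kind = "linear"
        for deg, kind in ((degree, "loess"), (1, "loess_degree1")):
            if deg > degree:
                continue
            try:
                self._model = fit_loess(x, y, span=span, degree=deg)
                self.kind = kind if deg == degree else "loess_degree1"
                break
            except InsufficientDataError:
                continue
        if self._model is None:
            # average replicate y at duplicate x, then straight lines
            df = pd.DataFrame({"x": x, "y": y}).groupby("x", sort=True).mean()
            self._lin_x = df.index.to_numpy()
            self._lin_y = df["y"].to_numpy()

    def predict(self, grid) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        if self._model is not None:
            return self._model.predict(grid)
        out = np.interp(grid, self._lin_x, self._lin_y)
        out[(grid < self.x_min) | (grid > self.x_max)] = np.nan
        return out


@dataclass
class SlidingResult:
    grid: np.ndarray
    p_values: np.ndarray  # NaN where the density gate blocked the test
    n_group1: np.ndarray
    n_group2: np.ndarray
    subject_curves: pd.DataFrame  # subjects x grid, NaN outside a subject's range
    groups: dict[str, str]
    group_labels: tuple[str, str]
    fallback_subjects: dict[str, str] = field(default_factory=dict)
    dropped_subjects: tuple[str, ...] = ()
    x_name: str = "x"
    y_name: str = "y"

    def to_frame(self) -> pd.DataFrame:
        """Per-interval table: x, p_value, subjects per group."""
        return pd.DataFrame(
            {
                "x": self.grid,
                "p_value": self.p_values,
                "n_group1": self.n_group1,
                "n_group2": self.n_group2,
            }
        )


def fit_subject_splines(
    table: LongitudinalTable, params: SlidingParams | None = None
) -> dict[str, SubjectCurve]:
    """One curve per subject, with graceful degradation.

    Subjects whose data cannot support the requested loess degree fall
    back to degree 1, then to linear interpolation between their own
    observed points; subjects with fewer than 2 distinct x values are
    dropped with a warning.
    """
    params = params or SlidingParams()
    curves: dict[str, SubjectCurve] = {}
    df = table.df
    for subj, rows in table.subject_rows().items():
        x = df["x"].to_numpy()[rows]
        y = df["y"].to_numpy()[rows]
        try:
            curves[subj] = SubjectCurve(x, y, params.span, params.degree)
        except InsufficientDataError:
            warnings.warn(
                f"subject {subj!r} dropped: fewer than 2 distinct x values",
                stacklevel=2,
            )
    return curves


def interpolate_grid(
    curves: dict[str, SubjectCurve], ints: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Evaluate all subject curves on a grid spanning the union of ranges."""
    if not curves:
        raise InsufficientDataError("no subject curves to interpolate")
    lo = min(c.x_min for c in curves.values())
    hi = max(c.x_max for c in curves.values())
    grid = np.linspace(lo, hi, ints)
    matrix = pd.DataFrame(
        {subj: c.predict(grid) for subj, c in curves.items()}, index=grid
    ).T
    return grid, matrix


def two_sample_interval_p(values1, values2, method: str = "mann_whitney") -> float:
    """The per-interval two-sample test.

    Mann-Whitney U (two-sided) by default: exact enumeration when both
    samples have <= 8 values and no ties, otherwise the normal
    approximation with tie correction. ``welch_t`` selects Welch's
    unequal-variance t test instead.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if method == "welch_t":
        return float(stats.ttest_ind(v1, v2, equal_var=False).pvalue)
    pooled = np.concatenate([v1, v2])
    if np.unique(pooled).size == 1:
        return 1.0  # all values identical: no evidence of separation
    if np.unique(pooled).size == pooled.size and v1.size <= 8 and v2.size <= 8:
        mw_method = "exact"
    else:
        mw_method = "asymptotic"
    res = stats.mannwhitneyu(
        v1, v2, alternative="two-sided", method=mw_method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def interval_tests(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    params: SlidingParams,
    group_labels: tuple[str, str],
) -> SlidingResult:
    """Run the density-gated two-sample test at every grid point."""
    grid = matrix.columns.to_numpy(dtype=float)
    missing = set(matrix.index) - set(groups)
    if missing:
        raise ValueError(f"subjects without a group label: {sorted(missing)[:5]}")
    lab1, lab2 = group_labels
    rows1 = [s for s in matrix.index if groups[s] == lab1]
    rows2 = [s for s in matrix.index if groups[s] == lab2]
    vals1 = matrix.loc[rows1].to_numpy()
    vals2 = matrix.loc[rows2].to_numpy()
    n1 = np.isfinite(vals1).sum(axis=0)
    n2 = np.isfinite(vals2).sum(axis=0)
    p = np.full(grid.shape, np.nan)
    for i in range(grid.size):
        if n1[i] >= params.test_density and n2[i] >= params.test_density:
            g1 = vals1[np.isfinite(vals1[:, i]), i]
            g2 = vals2[np.isfinite(vals2[:, i]), i]
            p[i] = two_sample_interval_p(g1, g2, params.interval_test)
    return SlidingResult(
        grid=grid,
        p_values=p,
        n_group1=n1.astype(int),
        n_group2=n2.astype(int),
        subject_curves=matrix,
        groups=dict(groups),
        group_labels=group_labels,
    )


def sliding_spliner(
    pair: GroupPair, params: SlidingParams | None = None, **overrides
) -> SlidingResult:
    """Localize where two groups' trajectories diverge along x."""
    if params is None:
        params = SlidingParams(**overrides)
    elif overrides:
        params = SlidingParams(**{**params.__dict__, **overrides})
    curves: dict[str, SubjectCurve] = {}
    groups: dict[str, str] = {}
    dropped: tuple[str, ...] = ()
    for tab, label in (
        (pair.group1_table, pair.group1_label),
        (pair.group2_table, pair.group2_label),
    ):
        ft, drop = filter_low_prevalence(tab, params.cut_low)
        dropped += drop
        sub = fit_subject_splines(ft, params)
        curves.update(sub)
        groups.update({s: label for s in sub})
    grid, matrix = interpolate_grid(curves, params.ints)
    # reindex the matrix columns back onto the grid values
    matrix.columns = grid
    result = interval_tests(
        matrix, groups, params, (pair.group1_label, pair.group2_label)
    )
    result.fallback_subjects = {
        s: c.kind for s, c in curves.items() if c.kind != "loess"
    }
    result.dropped_subjects = dropped
    t1 = pair.group1_table
    result.x_name = t1.column_names.get("x", "x")
    result.y_name = t1.column_names.get("y", "y")
    return result
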