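"""Single-group non-zero-trend test.

A loess curve is fit to the pooled observations of one group and
evaluated on an even grid across the observed x range. The statistic is
the signed sum of (curve - baseline) over the grid, where the baseline
is the flat line through the curve's value at the first grid point: a
trajectory that does not meaningfully increase or decrease stays near
its own start, so the area stays small. The null is built by shuffling
each subject's responses across that subject's own time points
(within-subject permutation), refitting, and measuring each permuted
curve against its own start; the p-value is two-sided on |area|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import SUBJECT, LongitudinalTable, filter_low_prevalence
from .errors import InsufficientDataError
from .loess import DEFAULT_DEGREE, DEFAULT_SPAN, fit_loess

logger = logging.getLogger(__name__)


@dataclass
class TrendParams:
    n_permutations: int = 999
    ints: int = 1000
    span: float = DEFAULT_SPAN
    degree: int = DEFAULT_DEGREE
    cut_low: int = 0
    mean_center: bool = False
    seed: int | None = None
    retain_permutations: int = 100

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.ints < 2:
            raise ValueError("ints must be >= 2")


@dataclass
class TrendResult:
    p_value: float
    observed_area: float
    permuted_areas: np.ndarray
    grid: np.ndarray
    spline: np.ndarray
    baseline_value: float
    n_subjects: int
    permuted_curves: list[dict] = field(default_factory=list)
    dropped_subjects: tuple[str, ...] = ()
    x_name: str = "x"
    y_name: str = "y"

    @property
    def trend_direction(self) -> str:
        return "increasing" if self.observed_area > 0 else "decreasing"

    def to_dict(self) -> dict:
        return {
            "test": "trendyspliner",
            "p_value": self.p_value,
            "observed_area": self.observed_area,
            "trend_direction": self.trend_direction,
            "baseline_value": self.baseline_value,
            "n_subjects": self.n_subjects,
            "n_permutations": len(self.permuted_areas),
            "dropped_subjects": list(self.dropped_subjects),
            "permuted_areas": [float(v) for v in self.permuted_areas],
            "grid": [float(v) for v in self.grid],
            "spline": [float(v) for v in self.spline],
        }


def mean_center(table: LongitudinalTable) -> LongitudinalTable:
    """Shift every subject's mean to the grand mean of all observations.

    Removes between-subject baseline offsets while preserving each
    subject's internal trajectory shape exactly.
    """
    df = table.df
    grand = df["y"].mean()
    centered = df["y"] - df.groupby(SUBJECT)["y"].transform("mean") + grand
    return table.with_y(centered.to_numpy())


def trend_area(curve: np.ndarray, baseline_value: float) -> float:
    """Signed sum over the grid of (curve - flat baseline at the start)."""
    curve = np.asarray(curve, dtype=float)
    if not np.isfinite(curve).all():
        raise ValueError("curve must have no missing values")
    return float((curve - baseline_value).sum())


def permute_within_subject(
    table: LongitudinalTable, rng: np.random.Generator
) -> LongitudinalTable:
    """Shuffle each subject's y values across its own x values."""
    y = table.y.copy()
    for _, rows in sorted(table.subject_rows().items()):
        y[rows] = y[rng.permutation(rows)]
    return table.with_y(y)


def _permute_y(y: np.ndarray, subject_rows: list[np.ndarray], rng) -> np.ndarray:
    out = y.copy()
    for rows in subject_rows:
        out[rows] = y[rng.permutation(rows)]
    return out


def _fit_area(x, y, grid, span, degree):
    model = fit_loess(x, y, span=span, degree=degree)
    curve = model.predict(grid)
    baseline = float(curve[0])
    return curve, baseline, trend_area(curve, baseline)


def trendyspliner(
    table: LongitudinalTable, params: TrendParams | None = None, **overrides
) -> TrendResult:
    """Test for a non-zero overall trend in one group's responses."""
    if params is None:
        params = TrendParams(**overrides)
    elif overrides:
        params = TrendParams(**{**params.__dict__, **overrides})
    table, dropped = filter_low_prevalence(table, params.cut_low)
    if params.mean_center:
        table = mean_center(table)
    x, y = table.x, table.y
    if np.unique(x).size < params.degree + 2:
        raise InsufficientDataError(
            f"need at least {params.degree + 2} distinct x values to fit the "
            "group spline"
        )
    grid = np.linspace(x.min(), x.max(), params.ints)
    curve, baseline, observed = _fit_area(x, y, grid, params.span, params.degree)

    # permute within canonically ordered subjects so the draw sequence
    # does not depend on input row order
    subject_rows = [r for _, r in sorted(table.subject_rows().items())]
    rng = np.random.default_rng(params.seed)
    m = params.n_permutations
    permuted = np.empty(m)
    retained: list[dict] = []
    for i in range(m):
        yp = _permute_y(y, subject_rows, rng)
        p_curve, p_base, p_area = _fit_area(x, yp, grid, params.span, params.degree)
        permuted[i] = p_area
        if len(retained) < params.retain_permutations:
            retained.append({"grid": grid, "curve": p_curve, "baseline": p_base})

    p = (int((np.abs(permuted) >= abs(observed)).sum()) + 1) / (m + 1)
    return TrendResult(
        p_value=p,
        observed_area=observed,
        permuted_areas=permuted,
        grid=grid,
        spline=curve,
        baseline_value=baseline,
        n_subjects=table.n_subjects,
        permuted_curves=retained,
        dropped_subjects=dropped,
        x_name=table.column_names.get("x", "x"),
        y_name=table.column_names.get("y", "y"),
    )
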