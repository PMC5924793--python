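"""Overall two-group trajectory comparison by label permutation.

One loess curve is fit to each group's pooled observations; the test
statistic is the group distance — the sum over a shared interpolation
grid of absolute differences between the two curves. The null is built
by shuffling which subject belongs to which group (label permutation,
group sizes preserved) and recomputing the distance; the empirical
p-value uses add-one smoothing so its floor is 1/(m + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import GroupPair, filter_low_prevalence
from .errors import InsufficientDataError, NoOverlapError, SparseGroupError
from .loess import DEFAULT_DEGREE, DEFAULT_SPAN, fit_loess

logger = logging.getLogger(__name__)

DEFAULT_CUT_SPARSE = 4  # a degree-2 local fit is underdetermined below 4 points


@dataclass
class PermuParams:
    """Parameters of the two-group permutation test."""

    n_permutations: int = 999
    ints: int = 1000
    test_direction: str = "more"
    span: float = DEFAULT_SPAN
    degree: int = DEFAULT_DEGREE
    cut_low: int = 0
    cut_sparse: int = DEFAULT_CUT_SPARSE
    seed: int | None = None
    retain_permutations: int = 100

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.ints < 2:
            raise ValueError("ints must be >= 2")
        if self.test_direction not in ("more", "less"):
            raise ValueError("test_direction must be 'more' or 'less'")
        if self.cut_sparse < 4:
            raise ValueError("cut_sparse must be >= 4")


@dataclass
class PermuTestResult:
    p_value: float
    observed_distance: float
    permuted_distances: np.ndarray
    grid: np.ndarray
    spline1: np.ndarray
    spline2: np.ndarray
    direction: str
    group_labels: tuple[str, str]
    n_subjects_per_group: tuple[int, int]
    n_redrawn: int
    permuted_curves: list[dict] = field(default_factory=list)
    dropped_subjects: tuple[str, ...] = ()
    x_name: str = "x"
    y_name: str = "y"

    def to_dict(self) -> dict:
        return {
            "test": "permuspliner",
            "p_value": self.p_value,
            "observed_distance": self.observed_distance,
            "direction": self.direction,
            "group_labels": list(self.group_labels),
            "n_subjects_per_group": list(self.n_subjects_per_group),
            "n_permutations": len(self.permuted_distances),
            "n_redrawn": self.n_redrawn,
            "dropped_subjects": list(self.dropped_subjects),
            "permuted_distances": [float(v) for v in self.permuted_distances],
            "grid": [float(v) for v in self.grid],
            "spline1": [float(v) for v in self.spline1],
            "spline2": [float(v) for v in self.spline2],
        }


def group_distance(curve1: np.ndarray, curve2: np.ndarray) -> float:
    """Sum of |y1 - y2| over grid points where both curves are defined."""
    curve1 = np.asarray(curve1, dtype=float)
    curve2 = np.asarray(curve2, dtype=float)
    if curve1.shape != curve2.shape:
        raise ValueError("curves must be evaluated on the same grid")
    shared = np.isfinite(curve1) & np.isfinite(curve2)
    if shared.sum() < 2:
        raise NoOverlapError(
            f"curves share only {int(shared.sum())} grid points (need >= 2)"
        )
    return float(np.abs(curve1[shared] - curve2[shared]).sum())


def permute_group_labels(assignments, rng: np.random.Generator):
    """Shuffle group membership without replacement (sizes preserved).

    ``assignments`` is either a plain label vector or a sequence of
    ``(subject_id, label)`` pairs. For pairs, labels are shuffled across
    subjects in canonical (sorted-by-subject) order so the draw depends
    only on the subject->label map, not on which group is listed first;
    the result is returned in the input order.
    """
    first = assignments[0] if len(assignments) else None
    as_pairs = isinstance(first, (tuple, list)) and len(first) == 2
    if as_pairs:
        subjects = np.array([str(s) for s, _ in assignments])
        labels = np.array([lab for _, lab in assignments])
    else:
        labels = np.asarray(assignments)
    if labels.size < 2:
        raise ValueError("need at least 2 subjects to permute")
    if np.unique(labels).size != 2:
        raise ValueError("exactly 2 labels must be present")
    if not as_pairs:
        return rng.permutation(labels)
    order = np.argsort(subjects, kind="stable")
    shuffled = rng.permutation(labels[order])
    new_labels = np.empty_like(labels)
    new_labels[order] = shuffled
    return list(zip(subjects.tolist(), new_labels.tolist()))


def empirical_p(observed: float, permuted, direction: str = "more") -> float:
    """Add-one smoothed permutation p-value; ties count against rejection."""
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("permuted distances must be non-empty")
    if direction == "more":
        b = int((permuted >= observed).sum())
    elif direction == "less":
        b = int((permuted <= observed).sum())
    else:
        raise ValueError("direction must be 'more' or 'less'")
    return (b + 1) / (permuted.size + 1)


class _GroupedData:
    """Flat numpy view of the pooled observations for fast permutation."""

    def __init__(self, pair: GroupPair, cut_low: int):
        tabs = []
        self.dropped: tuple[str, ...] = ()
        for t in (pair.group1_table, pair.group2_table):
            ft, dropped = filter_low_prevalence(t, cut_low)
            tabs.append(ft)
            self.dropped = self.dropped + dropped
        rows1, rows2 = tabs[0], tabs[1]
        self.x = np.concatenate([rows1.x, rows2.x])
        self.y = np.concatenate([rows1.y, rows2.y])
        subj_rows_1 = rows1.subject_rows()
        subj_rows_2 = {s: r + rows1.n_rows for s, r in rows2.subject_rows().items()}
        label_of = {s: pair.group1_label for s in subj_rows_1}
        label_of.update({s: pair.group2_label for s in subj_rows_2})
        rows_of = {**subj_rows_1, **subj_rows_2}
        # canonical subject order: permutation draws depend only on the
        # subject->label map, not on which group was listed first
        self.subjects = sorted(rows_of)
        self.row_idx = [rows_of[s] for s in self.subjects]
        self.labels = np.array([label_of[s] for s in self.subjects])
        self.n1 = len(subj_rows_1)
        self.n2 = len(subj_rows_2)

    def group_xy(self, labels: np.ndarray, label: str):
        idx = np.concatenate(
            [r for r, lab in zip(self.row_idx, labels) if lab == label]
        )
        return self.x[idx], self.y[idx]


def _evaluate_split(data, labels, pair, params):
    """Fit both group curves and measure their distance on a shared grid.

    The grid spans the intersection of the two groups' x ranges and is
    recomputed for every permutation (no-extrapolation rule applied to
    group curves).
    """
    x1, y1 = data.group_xy(labels, pair.group1_label)
    x2, y2 = data.group_xy(labels, pair.group2_label)
    for lab, xg in ((pair.group1_label, x1), (pair.group2_label, x2)):
        if xg.size < params.cut_sparse:
            raise SparseGroupError(
                f"group {lab!r} has {xg.size} observations "
                f"(cut_sparse={params.cut_sparse})"
            )
    m1 = fit_loess(x1, y1, span=params.span, degree=params.degree)
    m2 = fit_loess(x2, y2, span=params.span, degree=params.degree)
    lo = max(m1.x_min, m2.x_min)
    hi = min(m1.x_max, m2.x_max)
    if not lo < hi:
        raise NoOverlapError("the two groups' x ranges do not overlap")
    grid = np.linspace(lo, hi, params.ints)
    c1 = m1.predict(grid)
    c2 = m2.predict(grid)
    return grid, c1, c2, group_distance(c1, c2)


def permuspliner(pair: GroupPair, params: PermuParams | None = None, **overrides) -> PermuTestResult:
    """Test whether two groups' trajectories differ more (or less) than chance.

    Keyword overrides are applied on top of ``params`` (or the defaults),
    e.g. ``permuspliner(pair, n_permutations=199, seed=7)``.
    """
    if params is None:
        params = PermuParams(**overrides)
    elif overrides:
        params = PermuParams(**{**params.__dict__, **overrides})
    data = _GroupedData(pair, params.cut_low)
    if data.n1 < 1 or data.n2 < 1:
        raise SparseGroupError("both groups need at least one subject after cut_low")
    rng = np.random.default_rng(params.seed)

    grid, c1, c2, observed = _evaluate_split(data, data.labels, pair, params)

    m = params.n_permutations
    permuted = np.empty(m)
    retained: list[dict] = []
    n_redrawn = 0
    max_attempts = 100 * m + 1000
    attempts = 0
    i = 0
    while i < m:
        attempts += 1
        if attempts > max_attempts:
            raise SparseGroupError(
                f"exceeded {max_attempts} permutation attempts; groups too "
                "sparse to permute"
            )
        labs = permute_group_labels(data.labels, rng)
        try:
            g, p1, p2, dist = _evaluate_split(data, labs, pair, params)
        except (SparseGroupError, NoOverlapError, InsufficientDataError):
            n_redrawn += 1
            continue
        permuted[i] = dist
        if len(retained) < params.retain_permutations:
            retained.append(
                {"grid": g, "curve1": p1, "curve2": p2, "absdiff": np.abs(p1 - p2)}
            )
        i += 1

    p = empirical_p(observed, permuted, params.test_direction)
    if n_redrawn:
        logger.info("redrew %d failed permutations", n_redrawn)
    t1 = pair.group1_table
    return PermuTestResult(
        p_value=p,
        observed_distance=observed,
        permuted_distances=permuted,
        grid=grid,
        spline1=c1,
        spline2=c2,
        direction=params.test_direction,
        group_labels=(pair.group1_label, pair.group2_label),
        n_subjects_per_group=(data.n1, data.n2),
        n_redrawn=n_redrawn,
        permuted_curves=retained,
        dropped_subjects=data.dropped,
        x_name=t1.column_names.get("x", "x"),
        y_name=t1.column_names.get("y", "y"),
    )
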