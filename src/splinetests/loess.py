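"""Local-polynomial (loess) smoothing with tricube weights.

At a query point ``q`` the predictor selects the ``ceil(span * n)``
nearest training points (clamped so the local system stays solvable),
weights them by the tricube kernel ``w = (1 - (d/d_max)^3)^3`` with
``d_max`` the largest selected distance, fits a weighted least-squares
polynomial of the model degree centered at ``q``, and reports its value
at ``q``. Evaluation is strictly pointwise — no interpolation surface —
and never extrapolates: queries outside the fitted x range return NaN.

Points tied with the cutoff distance ``d_max`` receive tricube weight
exactly zero, so weighting all points with the clipped kernel is
identical to "select the k nearest, taking all points tied at the
cutoff". When every selected distance is zero (all neighbors stacked at
``q``) the prediction is the plain mean of the stacked responses.

Singular local systems fall back to the next lower degree and finally
to the tricube-weighted mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError

DEFAULT_SPAN = 0.75
DEFAULT_DEGREE = 2

# relative condition-number ceiling before dropping to a lower degree
_MAX_COND = 1e10


@dataclass(frozen=True)
class LoessModel:
    """A fitted loess smoother; prediction is defined on [x_min, x_max]."""

    xs: np.ndarray
    ys: np.ndarray
    span: float
    degree: int
    x_min: float = field(init=False)
    x_max: float = field(init=False)
    k: int = field(init=False)

    def __post_init__(self):
        n = len(self.xs)
        object.__setattr__(self, "x_min", float(self.xs[0]))
        object.__setattr__(self, "x_max", float(self.xs[-1]))
        k = int(min(n, max(self.degree + 2, math.ceil(self.span * n))))
        object.__setattr__(self, "k", k)

    def predict(self, x_new) -> np.ndarray:
        return predict_loess(self, x_new)


def fit_loess(x, y, span: float = DEFAULT_SPAN, degree: int = DEFAULT_DEGREE) -> LoessModel:
    """Validate and store the training data sorted by x.

    Requires at least ``degree + 2`` distinct x values so every local
    weighted system is overdetermined. Duplicate x values are retained
    and weighted individually.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n_distinct = np.unique(x).size
    if n_distinct < degree + 2:
        raise InsufficientDataError(
            f"need at least {degree + 2} distinct x values for degree {degree}, "
            f"got {n_distinct}"
        )
    order = np.argsort(x, kind="stable")
    return LoessModel(xs=x[order], ys=y[order], span=span, degree=degree)


def _wls_at_points(xc: np.ndarray, w: np.ndarray, y: np.ndarray, degree: int):
    """Batched weighted polynomial fits centered at each query.

    xc : (nq, n) training x minus query x (scaled by the bandwidth);
    w : (nq, n) tricube weights; y : (n,) responses. Solves each local
    weighted least-squares problem by QR of the sqrt-weighted design.
    Returns (values at the query, ok mask); a row is not ok when its
    local system is singular or ill-conditioned.
    """
    p = degree + 1
    nq = xc.shape[0]
    vals = np.full(nq, np.nan)
    sw = np.sqrt(w)
    if p == 1:
        denom = (w).sum(axis=1)
        ok = denom > 0
        vals[ok] = (w @ y)[ok] / denom[ok]
        return vals, ok
    cols = [sw]
    for _ in range(degree):
        cols.append(cols[-1] * xc)
    A = np.stack(cols, axis=2)  # (nq, n, p) sqrt-weighted centered design
    b = sw * y[None, :]
    try:
        Q, R = np.linalg.qr(A)
    except np.linalg.LinAlgError:  # pragma: no cover - qr rarely fails outright
        return vals, np.zeros(nq, dtype=bool)
    diag = np.abs(np.diagonal(R, axis1=1, axis2=2))
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (diag.min(axis=1) > 0) & (diag.max(axis=1) / diag.min(axis=1) < _MAX_COND)
    ok &= np.isfinite(diag).all(axis=1)
    if ok.any():
        rhs = np.einsum("qnp,qn->qp", Q[ok], b[ok])
        beta = np.linalg.solve(R[ok], rhs[..., None])
        vals[ok] = beta[:, 0, 0]
    ok &= np.isfinite(vals)
    vals[~ok] = np.nan
    return vals, ok


def predict_loess(model: LoessModel, x_new) -> np.ndarray:
    """Evaluate the smoother; NaN outside [x_min, x_max] (no extrapolation)."""
    q = np.atleast_1d(np.asarray(x_new, dtype=float))
    out = np.full(q.shape, np.nan)
    inside = np.isfinite(q) & (q >= model.x_min) & (q <= model.x_max)
    if not inside.any():
        return out
    qi = q[inside]
    xs, ys, k = model.xs, model.ys, model.k
    n = xs.size

    d = np.abs(xs[None, :] - qi[:, None])  # (nq, n)
    if k < n:
        dmax = np.partition(d, k - 1, axis=1)[:, k - 1]
    else:
        dmax = d.max(axis=1)
    vals = np.full(qi.shape, np.nan)

    flat = dmax == 0.0  # >= k training points exactly at the query
    if flat.any():
        for i in np.flatnonzero(flat):
            vals[i] = ys[d[i] == 0.0].mean()

    todo = ~flat
    if todo.any():
        t = d[todo] / dmax[todo, None]
        base = np.clip(1.0 - t * t * t, 0.0, None)
        w = base * base * base
        # local coordinates scaled by the bandwidth: same polynomial value
        # at the query (beta0), much better conditioned normal equations
        xc = (xs[None, :] - qi[todo, None]) / dmax[todo, None]
        sub_vals = np.full(int(todo.sum()), np.nan)
        remaining = np.ones(sub_vals.shape, dtype=bool)
        for deg in range(model.degree, 0, -1):
            if not remaining.any():
                break
            v, ok = _wls_at_points(xc[remaining], w[remaining], ys, deg)
            idx = np.flatnonzero(remaining)
            sub_vals[idx[ok]] = v[ok]
            remaining[idx[ok]] = False
        if remaining.any():  # final fallback: tricube-weighted mean
            idx = np.flatnonzero(remaining)
            wsum = w[idx].sum(axis=1)
            safe = wsum > 0
            sub_vals[idx[safe]] = (w[idx[safe]] @ ys) / wsum[safe]
            for i in idx[~safe]:
                # every neighbor tied at the cutoff: all tricube weights
                # vanish; use the plain mean of the selected points
                qrow = np.flatnonzero(todo)[i]
                sel = d[qrow] <= dmax[qrow]
                sub_vals[i] = ys[sel].mean()
        vals[todo] = sub_vals

    out[inside] = vals
    if np.isscalar(x_new) or np.ndim(x_new) == 0:
        return out
    return out
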