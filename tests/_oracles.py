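"""Independent reference implementations used only by the tests.

These are deliberately written with different algorithms and libraries
than the package (lstsq on an uncentered-but-shifted Vandermonde design
vs. batched QR on bandwidth-scaled coordinates; explicit combinatorial
enumeration vs. scipy) so that agreement is evidence of correctness.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def loess_oracle(x, y, span: float, degree: int, q: float) -> float:
    """Brute-force tricube-weighted polynomial least squares at one point."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    k = min(n, max(degree + 2, math.ceil(span * n)))
    d = np.abs(x - q)
    dmax = np.sort(d)[k - 1]
    if dmax == 0:
        return float(y[d == 0].mean())
    sel = d <= dmax  # the k nearest plus every point tied at the cutoff
    w = (1.0 - (d[sel] / dmax) ** 3) ** 3
    sw = np.sqrt(w)
    design = np.vander(x[sel] - q, degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(sw[:, None] * design, sw * y[sel], rcond=None)
    return float(beta[0])


def mann_whitney_exact_two_sided(a, b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (no ties allowed)."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"
    n1 = len(a)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}

    def u_stat(group_ranks):
        r = sum(group_ranks)
        return r - n1 * (n1 + 1) / 2

    observed = u_stat([ranks[v] for v in a])
    mu = n1 * len(b) / 2
    dev = abs(observed - mu)
    total = 0
    hits = 0
    all_ranks = list(range(1, len(pooled) + 1))
    for combo in combinations(all_ranks, n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / total
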