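"""Pre-configured result plots.

Three views mirror the tests: observed group curves over translucent
permuted curves, the observed pointwise distance over permuted distance
traces, and the per-interval p-value scatter with density-scaled points.
The image format follows the output extension (png/svg/pdf).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import SplineTestError
from .permuspliner import PermuTestResult
from .sliding import SlidingResult
from .trendy import TrendResult

_PERM_STYLE = dict(color="black", alpha=0.08, linewidth=0.8, zorder=1)


def _require_permuted(result) -> None:
    if not result.permuted_curves:
        raise SplineTestError(
            "no permuted curves were retained; rerun with retain_permutations > 0"
        )


def plot_permsplines(result: PermuTestResult | TrendResult, path: str | Path) -> Path:
    """Observed spline(s) drawn over translucent permuted splines."""
    _require_permuted(result)
    fig, ax = plt.subplots(figsize=(6, 4))
    if isinstance(result, TrendResult):
        for pc in result.permuted_curves:
            ax.plot(pc["grid"], pc["curve"], **_PERM_STYLE)
        ax.axhline(
            result.baseline_value, color="gray", linestyle=":", linewidth=1, zorder=2
        )
        ax.plot(
            result.grid, result.spline, color="crimson", linewidth=2, zorder=3,
            label=f"observed (p = {result.p_value:.3g})",
        )
    else:
        for pc in result.permuted_curves:
            ax.plot(pc["grid"], pc["curve1"], **_PERM_STYLE)
            ax.plot(pc["grid"], pc["curve2"], **_PERM_STYLE)
        lab1, lab2 = result.group_labels
        ax.plot(result.grid, result.spline1, color="crimson", linewidth=2,
                zorder=3, label=str(lab1))
        ax.plot(result.grid, result.spline2, color="steelblue", linewidth=2,
                zorder=3, label=str(lab2))
        ax.set_title(f"p = {result.p_value:.3g}")
    ax.set_xlabel(result.x_name)
    ax.set_ylabel(result.y_name)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_distance(result: PermuTestResult, path: str | Path) -> Path:
    """Observed pointwise |group difference| over permuted traces."""
    _require_permuted(result)
    fig, ax = plt.subplots(figsize=(6, 4))
    for pc in result.permuted_curves:
        ax.plot(pc["grid"], pc["absdiff"], **_PERM_STYLE)
    observed = np.abs(np.asarray(result.spline1) - np.asarray(result.spline2))
    ax.plot(result.grid, observed, color="crimson", linewidth=2, zorder=3,
            label="observed distance")
    ax.set_xlabel(result.x_name)
    ax.set_ylabel(f"|difference in {result.y_name}|")
    ax.set_title(f"group distance p = {result.p_value:.3g}")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_sliding_pvals(result: SlidingResult, path: str | Path) -> Path:
    """p-value vs x on a log scale; point area tracks contributing subjects.

    Gated intervals (too few subjects in either group) are not drawn;
    a dotted reference line marks p = 0.05.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    present = np.isfinite(result.p_values)
    if not present.any():
        warnings.warn("all intervals were gated by test_density; nothing to draw")
        ax.annotate(
            "no interval met the test_density requirement",
            xy=(0.5, 0.5), xycoords="axes fraction", ha="center",
        )
    else:
        n_total = result.n_group1[present] + result.n_group2[present]
        ax.scatter(
            result.grid[present],
            result.p_values[present],
            s=6.0 * n_total,  # point area proportional to data density
            alpha=0.7,
            color="steelblue",
            edgecolor="none",
        )
        ax.set_yscale("log")
        ax.axhline(0.05, color="black", linestyle=":", linewidth=1)
        ax.set_ylim(top=1.5)
    ax.set_xlabel(result.x_name)
    ax.set_ylabel("p-value")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
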