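"""Seeded synthetic longitudinal datasets.

Three families of scenarios, all pure functions of their seed (NumPy
PCG64 generator, pinned by ``np.random.default_rng``):

* a two-group perturbation study — a control group of pure Gaussian
  noise around a flat baseline and a perturbed group with one or two
  localized Gaussian bumps whose amplitude is a multiple (1x/2x/4x) of
  the noise standard deviation;
* an exchangeable null — both groups drawn from the identical noise
  process, for type-I-error calibration;
* a monotone trend — per-subject random intercepts plus a common linear
  slope, for the trend test and its mean-centering option.

Each subject is observed at jittered, approximately evenly spaced time
points on the study interval, emulating uncoordinated sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import LongitudinalTable

CONDITION = "condition"
CONTROL = "control"
PERTURBED = "perturbed"

# default perturbation geometry: localized bumps late in the series,
# narrow enough that a 1x bump sits near the detection limit while a 4x
# bump is unambiguous; the two-region bumps are close enough that their
# opposite signs partially cancel under group-level smoothing, making
# the two-region scenario the harder one at low magnitude
ONE_REGION = ((0.75, 0.05),)
TWO_REGIONS = ((0.60, 0.05), (0.75, 0.05))


@dataclass(frozen=True)
class PerturbationScenario:
    """Study conditions of the two-group perturbation experiment.

    ``regions`` holds one or two (center, width) pairs on ``x_range``;
    with two regions the second bump has the opposite sign. The bump
    amplitude is ``magnitude * noise_sd``.
    """

    n_per_group: int = 10
    n_timepoints: int = 30
    x_range: tuple[float, float] = (0.0, 1.0)
    noise_sd: float = 1.0
    magnitude: float = 4.0
    regions: tuple[tuple[float, float], ...] = ONE_REGION
    seed: int | None = None

    def __post_init__(self):
        lo, hi = self.x_range
        if not lo < hi:
            raise ValueError("x_range must be increasing")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 1 <= len(self.regions) <= 2:
            raise ValueError("one or two perturbation regions are supported")
        for center, width in self.regions:
            if width <= 0:
                raise ValueError("region widths must be positive")
            if not lo <= center <= hi:
                raise ValueError("region centers must lie inside x_range")


def _jittered_times(rng, n: int, lo: float, hi: float) -> np.ndarray:
    base = np.linspace(lo, hi, n)
    h = (hi - lo) / max(n - 1, 1)
    x = base + rng.uniform(-0.45 * h, 0.45 * h, size=n)
    return np.sort(np.clip(x, lo, hi))


def _bump(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((x - center) ** 2) / (2.0 * width**2))


def _as_table(records: list[dict], category: str | None) -> LongitudinalTable:
    df = pd.DataFrame.from_records(records)
    cats = [category] if category else []
    return LongitudinalTable(df, cats)


def simulate_perturbation_study(scenario: PerturbationScenario) -> LongitudinalTable:
    """Two groups: flat-baseline controls vs. bump-perturbed subjects.

    Perturbed subjects receive, for each region, a Gaussian bump of
    amplitude ``magnitude * noise_sd`` (the second region, if present,
    with opposite sign). ``magnitude=0`` degenerates to an exchangeable
    null. Category ``condition`` holds labels ``control``/``perturbed``.
    """
    rng = np.random.default_rng(scenario.seed)
    lo, hi = scenario.x_range
    amp = scenario.magnitude * scenario.noise_sd
    records: list[dict] = []
    for group, label in ((0, CONTROL), (1, PERTURBED)):
        for s in range(scenario.n_per_group):
            x = _jittered_times(rng, scenario.n_timepoints, lo, hi)
            y = rng.normal(0.0, scenario.noise_sd, size=x.size)
            if group == 1:
                for j, (center, width) in enumerate(scenario.regions):
                    sign = 1.0 if j == 0 else -1.0
                    y = y + sign * amp * _bump(x, center, width)
            sid = f"{label[:4]}_{s + 1:02d}"
            records += [
                {"subject": sid, "x": xi, "y": yi, CONDITION: label}
                for xi, yi in zip(x, y)
            ]
    return _as_table(records, CONDITION)


def simulate_null(
    n_per_group: int = 10,
    n_timepoints: int = 30,
    noise_sd: float = 1.0,
    seed: int | None = None,
    late_entry_fraction: float = 0.0,
    entry_point: float = 0.5,
) -> LongitudinalTable:
    """Two groups drawn from the identical Gaussian noise process.

    With ``late_entry_fraction > 0``, that fraction of each group's
    subjects is observed only from ``entry_point`` onward (staggered
    entry), thinning early-grid data density for density-gate checks.
    Category ``group`` holds labels ``a``/``b``.
    """
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    for label in ("a", "b"):
        n_late = int(round(late_entry_fraction * n_per_group))
        for s in range(n_per_group):
            lo = entry_point if s < n_late else 0.0
            x = _jittered_times(rng, n_timepoints, lo, 1.0)
            y = rng.normal(0.0, noise_sd, size=x.size)
            records += [
                {"subject": f"{label}_{s + 1:02d}", "x": xi, "y": yi, "group": label}
                for xi, yi in zip(x, y)
            ]
    return _as_table(records, "group")


def simulate_trend(
    n_subjects: int = 10,
    n_timepoints: int = 30,
    slope: float = 1.0,
    noise_sd: float = 1.0,
    subject_offset_sd: float = 0.0,
    seed: int | None = None,
) -> LongitudinalTable:
    """One group with a common linear trend and random intercepts.

    ``y = b_s + slope * x + noise`` with ``b_s ~ N(0, subject_offset_sd)``.
    ``slope=0`` gives a trend null; pairing it with a large
    ``subject_offset_sd`` produces the heterogeneous-baseline case that
    mean centering exists to fix.
    """
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    for s in range(n_subjects):
        b = rng.normal(0.0, subject_offset_sd) if subject_offset_sd > 0 else 0.0
        x = _jittered_times(rng, n_timepoints, 0.0, 1.0)
        y = b + slope * x + rng.normal(0.0, noise_sd, size=x.size)
        records += [
            {"subject": f"subj_{s + 1:02d}", "x": xi, "y": yi}
            for xi, yi in zip(x, y)
        ]
    return _as_table(records, None)
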