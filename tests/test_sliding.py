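import numpy as np
import pytest

from splinetests.data_model import split_groups
from splinetests.simulate import (
    PerturbationScenario,
    simulate_null,
    simulate_perturbation_study,
)
from splinetests.sliding import (
    fit_subject_splines,
    interpolate_grid,
    sliding_spliner,
    two_sample_interval_p,
)

from _oracles import mann_whitney_exact_two_sided
from conftest import make_table


class TestFitSubjectSplines:
    def test_full_loess_when_enough_points(self):
        rows = [("S1", float(i), float(i % 3)) for i in range(8)]
        rows += [("S2", float(i), 1.0) for i in range(8)]
        curves = fit_subject_splines(make_table(rows))
        assert curves["S1"].kind == "loess"
        assert curves["S1"].x_min == 0.0 and curves["S1"].x_max == 7.0

    def test_three_points_fall_back_to_degree_one(self):
        rows = [("S1", 0.0, 1.0), ("S1", 1.0, 2.0), ("S1", 2.0, 1.5),
                ("S2", 0.0, 1.0), ("S2", 1.0, 2.0)]
        curves = fit_subject_splines(make_table(rows))
        assert curves["S1"].kind == "loess_degree1"
        assert curves["S2"].kind == "linear"

    def test_single_point_subject_dropped_with_warning(self):
        rows = [("S1", 0.0, 1.0),
                ("S2", 0.0, 1.0), ("S2", 1.0, 2.0)]
        with pytest.warns(UserWarning, match="S1"):
            curves = fit_subject_splines(make_table(rows))
        assert "S1" not in curves and "S2" in curves


class TestInterpolateGrid:
    def test_no_extrapolation_beyond_subject_range(self):
        rows = [("S1", float(i), 1.0) for i in range(11)]          # [0, 10]
        rows += [("S2", float(i), 2.0) for i in range(5, 16)]      # [5, 15]
        curves = fit_subject_splines(make_table(rows))
        grid, matrix = interpolate_grid(curves, 16)
        assert grid[0] == 0.0 and grid[-1] == 15.0
        assert np.isnan(matrix.loc["S1", grid[grid > 10.0]]).all()
        assert np.isnan(matrix.loc["S2", grid[grid < 5.0]]).all()
        assert np.isfinite(matrix.loc["S1", grid[grid <= 10.0]]).all()

    def test_dense_case_has_no_missing(self):
        rows = [(f"S{s}", float(i), float(s)) for s in range(4) for i in range(6)]
        curves = fit_subject_splines(make_table(rows))
        _, matrix = interpolate_grid(curves, 20)
        assert np.isfinite(matrix.to_numpy()).all()

    def test_staggered_entry_halves_early_density(self):
        rows = [(f"a{s}", float(i), 0.0) for s in range(4) for i in range(11)]
        rows += [(f"b{s}", float(i), 0.0) for s in range(4) for i in range(5, 11)]
        curves = fit_subject_splines(make_table(rows))
        grid, matrix = interpolate_grid(curves, 11)
        early = np.isfinite(matrix.loc[:, grid[0]]).sum()
        late = np.isfinite(matrix.loc[:, grid[-1]]).sum()
        assert early == 4 and late == 8


class TestTwoSampleIntervalP:
    def test_exact_enumeration_most_extreme_4v4(self):
        p = two_sample_interval_p([1, 2, 3, 4], [10, 11, 12, 13])
        assert p == pytest.approx(2 / 70, abs=1e-12)
        # agreement with the combinatorial oracle
        assert p == pytest.approx(
            mann_whitney_exact_two_sided([1, 2, 3, 4], [10, 11, 12, 13]),
            abs=1e-12,
        )

    def test_identical_value_sets_give_one(self):
        assert two_sample_interval_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_oracle_agreement_on_random_untied_samples(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.normal(0, 1, int(rng.integers(3, 8)))
            b = rng.normal(0.5, 1, int(rng.integers(3, 8)))
            assert two_sample_interval_p(a, b) == pytest.approx(
                mann_whitney_exact_two_sided(a, b), abs=1e-12
            )

    def test_welch_option_detects_mean_shift(self):
        a = np.array([0.0, 0.1, -0.1, 0.05, -0.05])
        b = a + 3.0
        assert two_sample_interval_p(a, b, method="welch_t") < 1e-4


class TestDensityGate:
    @staticmethod
    def _staggered_pair():
        # group a: 5 subjects on [0, 10]; group b: 5 subjects, but only
        # 2 observed before x=5
        rows = []
        for s in range(5):
            rows += [(f"a{s}", float(i), float(s), {"g": "a"}) for i in range(11)]
        for s in range(2):
            rows += [(f"b{s}", float(i), float(s) + 5, {"g": "b"}) for i in range(11)]
        for s in range(2, 5):
            rows += [(f"b{s}", float(i), float(s) + 5, {"g": "b"})
                     for i in range(5, 11)]
        return split_groups(make_table(rows, ["g"]), "g", "a", "b")

    def test_gate_is_exact(self):
        pair = self._staggered_pair()
        res = sliding_spliner(pair, ints=11, test_density=3)
        gate = (res.n_group1 >= 3) & (res.n_group2 >= 3)
        assert np.array_equal(np.isfinite(res.p_values), gate)
        assert (~gate).any() and gate.any()
        # counts recorded even where gated
        assert res.n_group2[0] == 2

    def test_counts_never_exceed_group_sizes(self):
        pair = self._staggered_pair()
        res = sliding_spliner(pair, ints=25, test_density=2)
        assert res.n_group1.max() <= 5 and res.n_group2.max() <= 5
        assert (res.n_group1 + res.n_group2).max() <= 10


class TestSlidingLocalization:
    def test_minimum_p_lands_in_perturbed_region(self):
        hits = 0
        for rep in range(10):
            table = simulate_perturbation_study(
                PerturbationScenario(magnitude=4.0, seed=300 + rep)
            )
            pair = split_groups(table, "condition", "control", "perturbed")
            res = sliding_spliner(pair, ints=100)
            x_min_p = res.grid[np.nanargmin(res.p_values)]
            if 0.55 <= x_min_p <= 0.95:
                hits += 1
        assert hits >= 9

    def test_null_data_shows_no_consistent_pocket(self):
        table = simulate_null(n_per_group=8, n_timepoints=12, seed=21)
        pair = split_groups(table, "group", "a", "b")
        res = sliding_spliner(pair, ints=50)
        present = np.isfinite(res.p_values)
        assert np.nanmedian(res.p_values[present]) > 0.05
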