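import numpy as np
import pytest
from scipy import stats

from splinetests.data_model import split_groups
from splinetests.errors import NoOverlapError, SparseGroupError
from splinetests.permuspliner import (
    empirical_p,
    group_distance,
    permuspliner,
    permute_group_labels,
)
from splinetests.simulate import PerturbationScenario, simulate_perturbation_study

from conftest import make_table


class TestGroupDistance:
    def test_identical_curves_zero(self):
        c = np.linspace(0, 1, 50)
        assert group_distance(c, c) == 0.0

    def test_parallel_constants(self):
        assert group_distance(np.full(1000, 3.0), np.full(1000, 1.5)) == 1500.0

    def test_hand_summed_small_grid(self):
        grid = np.array([0.0, 0.5, 1.0])
        assert group_distance(grid, grid**2) == pytest.approx(0.25)

    def test_missing_points_excluded_pairwise(self):
        c1 = np.array([1.0, np.nan, 3.0, 4.0])
        c2 = np.array([2.0, 2.0, np.nan, 5.0])
        assert group_distance(c1, c2) == pytest.approx(1.0 + 1.0)

    def test_fewer_than_two_shared_raises(self):
        c1 = np.array([1.0, np.nan, np.nan])
        c2 = np.array([2.0, 2.0, np.nan])
        with pytest.raises(NoOverlapError):
            group_distance(c1, c2)


class TestPermuteGroupLabels:
    def test_label_multiset_conserved(self):
        rng = np.random.default_rng(0)
        pairs = [("s1", "A"), ("s2", "A"), ("s3", "B"), ("s4", "B")]
        out = permute_group_labels(pairs, rng)
        assert sorted(lab for _, lab in out) == ["A", "A", "B", "B"]
        assert [s for s, _ in out] == ["s1", "s2", "s3", "s4"]

    def test_uniform_over_assignments(self):
        # 4 subjects, labels {A,A,B,B}: 6 distinct assignments, each 1/6
        rng = np.random.default_rng(123)
        labels = np.array(["A", "A", "B", "B"])
        counts: dict[tuple, int] = {}
        for _ in range(3000):
            perm = tuple(permute_group_labels(labels, rng))
            counts[perm] = counts.get(perm, 0) + 1
        assert len(counts) == 6
        chi = stats.chisquare(list(counts.values()))
        assert chi.pvalue > 0.001

    def test_seeded_sequence_reproducible(self):
        labels = ["A", "A", "A", "B", "B"]
        draws1 = np.random.default_rng(9)
        draws2 = np.random.default_rng(9)
        for _ in range(10):
            a = permute_group_labels(labels, draws1)
            b = permute_group_labels(labels, draws2)
            assert a.tolist() == b.tolist()


class TestEmpiricalP:
    def test_two_exceedances_of_999_gives_0_003(self):
        permuted = np.concatenate([np.full(997, 0.5), [2.0, 3.0]])
        assert empirical_p(1.0, permuted, "more") == pytest.approx(0.003)

    def test_floor_is_one_over_m_plus_one(self):
        permuted = np.full(999, 0.1)
        assert empirical_p(5.0, permuted, "more") == pytest.approx(0.001)

    def test_observed_below_all_permuted_direction_more(self):
        assert empirical_p(0.0, np.arange(1, 100.0), "more") == 1.0

    def test_less_direction_mirrors_more(self):
        permuted = np.arange(1, 100.0)
        assert empirical_p(0.5, permuted, "less") == pytest.approx(1 / 100)
        assert empirical_p(1000.0, permuted, "less") == 1.0

    def test_ties_count_against_rejection(self):
        permuted = np.array([1.0, 1.0, 2.0])
        assert empirical_p(1.0, permuted, "more") == pytest.approx(1.0)


def _pair(seed=0, magnitude=4.0, **kw):
    table = simulate_perturbation_study(
        PerturbationScenario(magnitude=magnitude, seed=seed, **kw)
    )
    return split_groups(table, "condition", "control", "perturbed")


class TestPermuspliner:
    def test_reproducible_bit_for_bit(self):
        pair = _pair(seed=1, n_per_group=5, n_timepoints=8)
        r1 = permuspliner(pair, n_permutations=30, ints=100, seed=42)
        r2 = permuspliner(pair, n_permutations=30, ints=100, seed=42)
        assert np.array_equal(r1.permuted_distances, r2.permuted_distances)
        assert r1.p_value == r2.p_value

    def test_group_swap_symmetry(self):
        table = simulate_perturbation_study(
            PerturbationScenario(magnitude=2.0, seed=3, n_per_group=5,
                                 n_timepoints=8)
        )
        fwd = split_groups(table, "condition", "control", "perturbed")
        rev = split_groups(table, "condition", "perturbed", "control")
        r1 = permuspliner(fwd, n_permutations=50, ints=100, seed=7)
        r2 = permuspliner(rev, n_permutations=50, ints=100, seed=7)
        assert r1.observed_distance == pytest.approx(r2.observed_distance)
        assert np.allclose(r1.permuted_distances, r2.permuted_distances)
        assert r1.p_value == r2.p_value

    def test_p_within_attainable_bounds(self):
        pair = _pair(seed=2, n_per_group=5, n_timepoints=8, magnitude=0.0)
        r = permuspliner(pair, n_permutations=19, ints=100, seed=0)
        assert 1 / 20 <= r.p_value <= 1.0
        assert r.observed_distance >= 0
        assert (r.permuted_distances >= 0).all()

    def test_directions_are_complementary(self):
        pair = _pair(seed=4, n_per_group=6, n_timepoints=10)
        more = permuspliner(pair, n_permutations=49, ints=100, seed=5,
                            test_direction="more")
        less = permuspliner(pair, n_permutations=49, ints=100, seed=5,
                            test_direction="less")
        # counts of >= and <= overlap only at exact ties
        assert more.p_value + less.p_value >= 1.0

    def test_strong_perturbation_detected(self):
        pair = _pair(seed=6)
        r = permuspliner(pair, n_permutations=99, ints=200, seed=8)
        assert r.p_value == pytest.approx(1 / 100)

    def test_sparse_group_raises(self):
        rows = [("A1", 0.0, 1.0, {"g": "a"}), ("A1", 1.0, 1.0, {"g": "a"}),
                ("A2", 0.5, 1.0, {"g": "a"}),
                ("B1", 0.0, 2.0, {"g": "b"}), ("B1", 1.0, 2.2, {"g": "b"}),
                ("B2", 0.2, 2.0, {"g": "b"}), ("B2", 0.8, 2.1, {"g": "b"}),
                ("B3", 0.4, 2.0, {"g": "b"})]
        pair = split_groups(make_table(rows, ["g"]), "g", "a", "b")
        with pytest.raises(SparseGroupError):
            permuspliner(pair, n_permutations=9, cut_sparse=4)

    def test_disjoint_x_ranges_raise(self):
        rows = []
        for s in range(3):
            for x in np.linspace(0, 1, 5):
                rows.append((f"a{s}", x, 0.0, {"g": "a"}))
            for x in np.linspace(2, 3, 5):
                rows.append((f"b{s}", x, 0.0, {"g": "b"}))
        pair = split_groups(make_table(rows, ["g"]), "g", "a", "b")
        with pytest.raises(NoOverlapError):
            permuspliner(pair, n_permutations=9)

    def test_retained_curves_bounded(self):
        pair = _pair(seed=9, n_per_group=5, n_timepoints=8)
        r = permuspliner(pair, n_permutations=25, ints=50, seed=1,
                         retain_permutations=10)
        assert len(r.permuted_curves) == 10
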