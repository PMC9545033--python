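import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from evorepeat import GroupedSample, kruskal_wallis, levene_test, spearman_rho
from evorepeat.stats_tests import DegenerateInputError, InsufficientDataError, average_ranks


def _random_groups(rng, k=3, sizes=(8, 10, 12), scale=(1.0, 2.0, 0.5)):
    return GroupedSample(
        tuple(
            (f"g{j}", rng.normal(0.0, scale[j], size=sizes[j])) for j in range(k)
        )
    )


class TestAverageRanks:
    def test_matches_scipy_rankdata_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 5, size=12).astype(float)
            np.testing.assert_allclose(average_ranks(x), sps.rankdata(x))


class TestLevene:
    def test_equal_spreads_give_zero_statistic(self):
        s = GroupedSample.from_dict({"a": [0, 2, 4], "b": [10, 12, 14]})
        res = levene_test(s, center="mean")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_groups_are_degenerate(self):
        s = GroupedSample.from_dict({"a": [1, 1, 1], "b": [1, 1, 1]})
        res = levene_test(s)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_too_small_group_rejected(self):
        s = GroupedSample.from_dict({"a": [1.0], "b": [1, 2, 3]})
        with pytest.raises(InsufficientDataError):
            levene_test(s)

    @pytest.mark.parametrize("center", ["mean", "median"])
    def test_matches_scipy_oracle(self, center):
        rng = np.random.default_rng(3)
        for _ in range(25):
            s = _random_groups(rng)
            res = levene_test(s, center=center)
            stat, p = sps.levene(*(v for _, v in s.groups), center=center)
            assert res.statistic == pytest.approx(stat, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_statistic_is_anova_on_absolute_deviations(self):
        # independent route: one-way ANOVA on the |y - median| values
        rng = np.random.default_rng(9)
        s = _random_groups(rng)
        zs = [np.abs(v - np.median(v)) for _, v in s.groups]
        f, _ = sps.f_oneway(*zs)
        assert levene_test(s, center="median").statistic == pytest.approx(f, abs=1e-10)

    @given(shift=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_shifting_one_group(self, shift):
        rng = np.random.default_rng(4)
        groups = {"a": rng.normal(size=8), "b": rng.normal(size=8), "c": rng.normal(size=8)}
        base = levene_test(GroupedSample.from_dict(groups))
        groups["b"] = groups["b"] + shift
        shifted = levene_test(GroupedSample.from_dict(groups))
        assert shifted.statistic == pytest.approx(base.statistic, rel=1e-9, abs=1e-12)


class TestKruskalWallis:
    def test_equal_rank_sums_give_zero(self):
        s = GroupedSample.from_dict({"a": [1, 6], "b": [2, 5], "c": [3, 4]})
        assert kruskal_wallis(s).statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_ranked_example(self):
        # groups {1,2},{3,4},{5,6}: ranks 1..6, rank sums 3/7/11,
        # H = 12/(6*7) * (9/2 + 49/2 + 121/2) - 3*7 = 32/7
        s = GroupedSample.from_dict({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert kruskal_wallis(s).statistic == pytest.approx(32.0 / 7.0)

    def test_all_identical_is_degenerate(self):
        s = GroupedSample.from_dict({"a": [2, 2], "b": [2, 2]})
        with pytest.raises(DegenerateInputError):
            kruskal_wallis(s)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            groups = {f"g{j}": rng.integers(0, 6, size=7).astype(float) for j in range(3)}
            if len(np.unique(np.concatenate(list(groups.values())))) == 1:
                continue
            s = GroupedSample.from_dict(groups)
            res = kruskal_wallis(s)
            stat, p = sps.kruskal(*groups.values())
            assert res.statistic == pytest.approx(stat, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_two_groups_agree_with_rank_sum_normal_approximation(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=9)
            res = kruskal_wallis(GroupedSample.from_dict({"a": a, "b": b}))
            n1, n2 = len(a), len(b)
            N = n1 + n2
            ranks = sps.rankdata(np.concatenate([a, b]))
            w = ranks[:n1].sum()
            z = (w - n1 * (N + 1) / 2) / np.sqrt(n1 * n2 * (N + 1) / 12.0)
            p_norm = 2 * sps.norm.sf(abs(z))
            assert res.p_value == pytest.approx(p_norm, abs=0.01)

    @given(
        scale=st.floats(0.1, 10.0),
        power=st.sampled_from([1.0, 3.0]),
    )
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_monotone_transforms(self, scale, power):
        rng = np.random.default_rng(17)
        groups = {f"g{j}": np.abs(rng.normal(size=6)) + 0.1 for j in range(3)}
        s1 = GroupedSample.from_dict(groups)
        s2 = GroupedSample.from_dict({k: (scale * v) ** power for k, v in groups.items()})
        assert kruskal_wallis(s2).statistic == pytest.approx(
            kruskal_wallis(s1).statistic, abs=1e-10
        )


class TestSpearman:
    @pytest.mark.parametrize(
        "x, y, expected",
        [((1, 2, 3), (1, 2, 3), 1.0), ((1, 2, 3), (3, 2, 1), -1.0)],
    )
    def test_perfect_orderings(self, x, y, expected):
        assert spearman_rho(x, y) == pytest.approx(expected)

    def test_tied_predicted_ranks_match_hand_pearson(self):
        # ranks of x=(1, 2.5, 2.5) are (1, 2.5, 2.5); ranks of y=(2,1,3)
        # are themselves; Pearson of those rank vectors is the oracle.
        x, y = (1.0, 2.5, 2.5), (2.0, 1.0, 3.0)
        rx, ry = np.array([1.0, 2.5, 2.5]), np.array([2.0, 1.0, 3.0])
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            x = rng.integers(0, 8, size=12).astype(float)
            y = rng.normal(size=12)
            if len(np.unique(x)) == 1:
                continue
            assert spearman_rho(x, y) == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-10)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r = spearman_rho(x, y)
        assert r == pytest.approx(spearman_rho(y, x))
        assert -1.0 <= r <= 1.0


class TestNullCalibration:
    def test_rejection_rates_at_nominal_level(self):
        # Under iid normal groups, both tests should reject at ~alpha.
        rng = np.random.default_rng(23)
        alpha, n_sims = 0.05, 2000
        rej_lev = rej_kw = 0
        for _ in range(n_sims):
            s = GroupedSample(tuple((f"g{j}", rng.normal(size=10)) for j in range(3)))
            rej_lev += levene_test(s).p_value < alpha
            rej_kw += kruskal_wallis(s).p_value < alpha
        assert abs(rej_lev / n_sims - alpha) < 0.02
        assert abs(rej_kw / n_sims - alpha) < 0.02
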