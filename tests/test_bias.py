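"""Occurrence tables, signed bias, indices, shape calls and rank tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

import mirspec.bias as bs
from mirspec import example_data as ex


def chi2_tail_oracle(c: float) -> float:
    """Upper-tail chi-square(1) probability by numeric integration of the
    density x^(-1/2) e^(-x/2) / sqrt(2 pi), independent of scipy.stats."""
    if c <= 0:
        return 1.0
    density = lambda x: math.exp(-x / 2.0) / math.sqrt(2.0 * math.pi * x)
    tail, _ = integrate.quad(density, c, np.inf, epsabs=1e-14, epsrel=1e-12)
    return tail


class TestCountOccurrences:
    def setup_method(self):
        self.g2h = pd.DataFrame(
            0, index=["g1", "g2"], columns=["h1", "h2"], dtype=int
        )
        self.levels = pd.Series([6, 2], index=["g1", "g2"])
        self.ranks = pd.Series([5, 3], index=["h1", "h2"])
        self.ages = pd.Series([1, 2], index=["h1", "h2"])

    def count(self, age):
        return bs.count_occurrences(
            self.g2h, self.levels, self.ranks, self.ages, age
        )

    def test_empty_matrix_gives_zero_table(self):
        assert self.count(1).counts.sum() == 0

    def test_single_pair_lands_in_its_cell(self):
        self.g2h.loc["g1", "h1"] = 1
        table = self.count(1)
        assert table.counts[5, 4] == 1  # level 6, rank 5
        assert table.counts.sum() == 1

    def test_other_age_excluded(self):
        self.g2h.loc["g1", "h2"] = 1  # h2 has age 2
        assert self.count(1).counts.sum() == 0
        assert self.count(2).counts[5, 2] == 1

    def test_missing_rank_errors(self):
        g2h = pd.DataFrame(0, index=["g1"], columns=["hX"])
        with pytest.raises(bs.BiasError, match="hX"):
            bs.count_occurrences(g2h, self.levels, self.ranks, self.ages, 1)


class TestLevelConversion:
    def test_group_means(self):
        counts = np.tile(np.arange(1.0, 12.0)[:, None], (1, 5))
        o = bs.OccurrenceTable(counts, "eleven_level")
        five = bs.convert_levels_to_ranks(o)
        assert list(five.counts[:, 0]) == [1, 3, 6, 9, 11]

    def test_all_ones(self):
        o = bs.OccurrenceTable(np.ones((11, 5)), "eleven_level")
        assert (bs.convert_levels_to_ranks(o).counts == 1).all()

    def test_top_level_passes_through(self):
        counts = np.zeros((11, 5))
        counts[10, :] = 7
        o = bs.OccurrenceTable(counts, "eleven_level")
        five = bs.convert_levels_to_ranks(o)
        assert list(five.counts[:, 0]) == [0, 0, 0, 0, 7]


class TestExpectedCounts:
    def test_independence_fixed_point(self):
        r, c = np.array([1.0, 2, 3, 4, 5]), np.array([5.0, 4, 3, 2, 1])
        o = bs.OccurrenceTable(np.outer(r, c), "five_rank")
        e = bs.expected_counts(o)
        np.testing.assert_allclose(e.expected, o.counts)

    def test_marginals_conserved(self):
        rng = np.random.default_rng(0)
        o = bs.OccurrenceTable(rng.integers(0, 50, (5, 5)) + 1.0, "five_rank")
        e = bs.expected_counts(o)
        np.testing.assert_allclose(
            e.expected.sum(axis=1), o.counts.sum(axis=1)
        )
        np.testing.assert_allclose(
            e.expected.sum(axis=0), o.counts.sum(axis=0)
        )
        assert math.isclose(e.expected.sum(), e.total)

    def test_empty_table_errors(self):
        o = bs.OccurrenceTable(np.zeros((5, 5)), "five_rank")
        with pytest.raises(bs.BiasError, match="empty"):
            bs.expected_counts(o)


class TestSignedBias:
    def test_zero_where_observed_equals_expected(self):
        b = bs.signed_bias(np.full((2, 2), 5.0), np.full((2, 2), 5.0))
        assert (b.bias == 0).all() and (b.chi2 == 0).all()

    @pytest.mark.parametrize(
        "o, e",
        [(20.0, 10.0), (2.0, 10.0), (1.0, 30.0), (30.0, 10.0)],
    )
    def test_matches_integration_oracle(self, o, e):
        b = bs.signed_bias(np.array([[o]]), np.array([[e]]))
        c = (o - e) ** 2 / e
        expected = -math.log10(chi2_tail_oracle(c))
        if o < e:
            expected = -expected
        assert b.bias[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_frozen_examples(self):
        # values computed with the integration oracle above
        up = bs.signed_bias(np.array([[20.0]]), np.array([[10.0]]))
        down = bs.signed_bias(np.array([[2.0]]), np.array([[10.0]]))
        assert up.bias[0, 0] == pytest.approx(2.80537, abs=1e-4)
        assert down.bias[0, 0] == pytest.approx(-1.94264, abs=1e-4)

    def test_zero_expected_flags(self):
        b = bs.signed_bias(
            np.array([[3.0, 0.0]]), np.array([[0.0, 0.0]])
        )
        assert b.not_available[0, 0]
        assert b.bias[0, 1] == 0.0

    def test_extreme_cell_capped(self):
        b = bs.signed_bias(np.array([[1e6]]), np.array([[1.0]]))
        assert b.capped[0, 0] and b.bias[0, 0] == 300.0

    @given(
        o=st.floats(min_value=0, max_value=100),
        e=st.floats(min_value=0.1, max_value=100),
    )
    @settings(deadline=None, max_examples=60)
    def test_antisymmetry(self, o, e):
        """Swapping observed and expected flips the sign, keeps |bias|."""
        if o == 0:
            o = 0.5
        fwd = bs.signed_bias(np.array([[o]]), np.array([[e]])).bias[0, 0]
        rev = bs.signed_bias(np.array([[e]]), np.array([[o]])).bias[0, 0]
        if o != e:
            # magnitudes differ because the Pearson denominator changes,
            # but signs must oppose
            assert np.sign(fwd) == -np.sign(rev)
        else:
            assert fwd == rev == 0


class TestIndicesAndShape:
    def bias_table(self, B, C):
        table = bs.BiasTable(
            chi2=np.asarray(C, float), bias=np.asarray(B, float),
            not_available=np.zeros((5, 5), bool),
            capped=np.zeros((5, 5), bool),
        )
        return table

    def full(self, col_b, col_c):
        B = np.zeros((5, 5))
        C = np.zeros((5, 5))
        B[:, 4] = col_b
        C[:, 4] = col_c
        return B, C

    def test_avoidance_direct_sum(self):
        B = np.zeros((5, 5)); C = np.zeros((5, 5))
        B[4, 0], B[4, 4] = 3.0, -2.0
        C[4, 0], C[4, 4] = 6.0, 4.0
        a = bs.avoidance_index(self.bias_table(B, C))
        assert a.value == 10.0
        assert a.components == {"C_top_top": 4.0, "C_top_mute": 6.0}

    @pytest.mark.parametrize(
        "b_mute, b_top", [(-1.0, -2.0), (3.0, 0.5), (0.0, -1.0)]
    )
    def test_avoidance_not_in_order(self, b_mute, b_top):
        B = np.zeros((5, 5)); C = np.ones((5, 5))
        B[4, 0], B[4, 4] = b_mute, b_top
        a = bs.avoidance_index(self.bias_table(B, C))
        assert a.status == bs.NOT_IN_ORDER

    @pytest.mark.parametrize(
        "column, expected",
        [
            ([-1, 2, 3, 2.5, -2], bs.LAMBDA),
            ([3, 1, 0.5, 1, 2], bs.VEE),
            ([0, 1, 5, 1, 2], bs.NEITHER),
        ],
    )
    def test_shape_calls(self, column, expected):
        assert bs.shape_call(column) == expected

    @given(
        st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False),
            min_size=5, max_size=5,
        )
    )
    @settings(deadline=None, max_examples=200)
    def test_lambda_vee_mutually_exclusive(self, column):
        call = bs.shape_call(column)
        inner, outer = np.array(column[1:4]), np.array([column[0], column[4]])
        is_lambda = inner.min() > outer.max()
        is_vee = inner.max() < outer.min()
        assert not (is_lambda and is_vee)
        assert call == (
            bs.LAMBDA if is_lambda else bs.VEE if is_vee else bs.NEITHER
        )

    def test_preference_components(self):
        h = bs.preference_index(
            [-1, 2, 3, 2.5, -2], [2, 4, 9, 6, 3]
        )
        assert h.value == 11.0
        assert h.components == {"H_rise": 9.0, "H_dive": 2.0}

    @pytest.mark.parametrize(
        "b", [[-1, -0.1, -3, -2, -2], [0.2, 2, 3, 2, -1], [-1, 2, 3, 2, 0.2]]
    )
    def test_preference_not_in_order(self, b):
        h = bs.preference_index(b, [1, 1, 1, 1, 1])
        assert h.status == bs.NOT_IN_ORDER

    def test_preference_argmax_tie_prefers_smaller_rank(self):
        h = bs.preference_index([-1, 3, 3, 1, -2], [5, 7, 9, 1, 2])
        assert h.components["H_rise"] == 7.0  # gene rank 2, not 3


def signed_rank_enumeration_oracle(diffs):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.array([x for x in diffs if x != 0.0])
    n = d.size
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    observed = ranks[d < 0].sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for s, r in zip(signs, ranks) if s))
    stats = np.array(stats)
    p_le = (stats <= observed + 1e-12).mean()
    p_ge = (stats >= observed - 1e-12).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestSignedRank:
    def test_table_values_avoidance(self):
        """Worked example: nine usable organ pairs, all favoring the older
        class, give the exact two-sided p of 2/2^9."""
        res = bs.paired_signed_rank_test(ex.AVOIDANCE_ANTE, ex.AVOIDANCE_EUTH)
        assert res.n == 9
        assert res.p == pytest.approx(0.00390625, rel=1e-12)
        assert round(res.p, 3) == 0.004

    def test_table_values_preference(self):
        res = bs.paired_signed_rank_test(ex.PREFERENCE_ANTE, ex.PREFERENCE_EUTH)
        assert res.n == 9
        assert res.p == pytest.approx(0.01171875, rel=1e-12)
        assert round(res.p, 2) == 0.01

    def test_all_pairs_undefined(self):
        res = bs.paired_signed_rank_test([None, None], [None, None])
        assert res.status == bs.NOT_AVAILABLE

    def test_single_undefined_side_scores_zero(self):
        res = bs.paired_signed_rank_test([5.0, None], [None, 3.0])
        # pairs become (5, 0) and (0, 3): one positive, one negative diff
        assert res.n == 2

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            n = int(rng.integers(1, 13))
            diffs = np.round(rng.normal(size=n), 1)  # induces ties and zeros
            ours = bs.wilcoxon_signed_rank(diffs)
            if ours.status is not None:
                assert all(d == 0 for d in diffs)
                continue
            assert ours.p == pytest.approx(
                signed_rank_enumeration_oracle(diffs), rel=1e-9
            )


def jt_permutation_oracle(groups, alternative="increasing"):
    """Exact permutation p for the trend statistic by enumerating every
    distinct assignment of the pooled values to the group sizes."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    sizes = [len(g) for g in groups]

    def statistic(parts):
        j = 0.0
        for a, b in itertools.combinations(parts, 2):
            diff = b[None, :] - a[:, None]
            j += (diff > 0).sum() + 0.5 * (diff == 0).sum()
        return j

    observed = statistic([np.asarray(g, float) for g in groups])
    count_ge = total = 0
    for perm in set(itertools.permutations(range(len(pooled)))):
        parts, pos = [], 0
        for s in sizes:
            parts.append(pooled[list(perm[pos : pos + s])])
            pos += s
        total += 1
        if statistic(parts) >= observed - 1e-9:
            count_ge += 1
    return count_ge / total


class TestJonckheereTerpstra:
    def test_two_groups_equal_mann_whitney(self):
        from scipy.stats import mannwhitneyu

        a, b = [1.0, 4.0, 2.5], [3.0, 5.0, 6.0, 2.5]
        res = bs.jonckheere_terpstra_test([a, b])
        u = mannwhitneyu(b, a, alternative="greater").statistic
        assert res.statistic == pytest.approx(u)

    def test_strict_separation_exact_p(self):
        """Perfectly ordered groups: only one of the 6!/(2!2!2!) = 90
        arrangements reaches the maximal statistic."""
        res = bs.jonckheere_terpstra_test([[1, 2], [3, 4], [5, 6]])
        assert res.p == pytest.approx(1 / 90)

    def test_identical_groups_no_trend(self):
        res = bs.jonckheere_terpstra_test([[1, 1], [1, 1], [1, 1]])
        assert res.p == pytest.approx(1.0)

    def test_empty_group_errors(self):
        with pytest.raises(bs.BiasError):
            bs.jonckheere_terpstra_test([[1.0], []])

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            groups = [
                list(np.round(rng.normal(loc=i, size=int(rng.integers(2, 4))), 1))
                for i in range(3)
            ]
            ours = bs.jonckheere_terpstra_test(groups, alternative="increasing")
            oracle = jt_permutation_oracle(groups)
            assert ours.p == pytest.approx(oracle, rel=1e-9)

    def test_normal_approximation_on_larger_samples(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(loc=i * 0.8, size=30) for i in range(4)]
        res = bs.jonckheere_terpstra_test(groups)
        assert res.p < 1e-4  # strong planted trend detected
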