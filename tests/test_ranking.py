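"""Rankings, classification, balances, significance, effect size, CLR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from matchrank.io import FeatureTable
from matchrank.matching import MatchedPairs
from matchrank.model import PosteriorDifferentials, summarize_draws
from matchrank.ranking import (
    classify_features,
    clr_pair_differences,
    compute_balance,
    consensus_classification,
    effect_size_and_p,
    pair_balance_differences,
    rank_differentials,
    significance_calls,
)


def _posterior(draws):
    """Wrap an (m, d) draw matrix as a PosteriorDifferentials (2 pseudo-chains)."""
    draws = np.asarray(draws, dtype=float)
    m, d = draws.shape
    chain = draws.reshape(2, m // 2, d)
    fids = [f"F{j}" for j in range(d)]
    return PosteriorDifferentials(fids, chain, summarize_draws(chain, fids))


class TestRanking:
    def test_sorted_descending_with_id_ties(self):
        post = _posterior(np.tile([0.5, -1.0, 2.0], (20, 1)))
        r = rank_differentials(post)
        assert r["feature"].tolist() == ["F2", "F0", "F1"]

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=(40, 6))
        a = rank_differentials(_posterior(draws))["feature"].tolist()
        b = rank_differentials(_posterior(draws + 3.7))["feature"].tolist()
        assert a == b

    def test_agrees_with_sort_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            means = rng.normal(size=8)
            post = _posterior(np.tile(means, (20, 1)))
            got = rank_differentials(post)["mean"].to_numpy()
            np.testing.assert_allclose(got, np.sort(means)[::-1], rtol=1e-12)


class TestClassification:
    def test_rule_application(self):
        draws = np.array([[1.0]] * 8 + [[-1.0]] * 2)
        assert classify_features(_posterior(draws)).iloc[0] == "case-associated"

    def test_symmetric_draws_neutral(self):
        draws = np.array([[1.0], [-1.0]] * 10)
        assert classify_features(_posterior(draws)).iloc[0] == "neutral"

    def test_boundary_inclusive(self):
        draws = np.array([[1.0]] * 7 + [[-1.0]] * 3)  # exactly 70%
        assert classify_features(_posterior(draws)).iloc[0] == "case-associated"

    def test_zero_draws_count_to_neither_side(self):
        draws = np.array([[1.0]] * 6 + [[0.0]] * 4)
        assert classify_features(_posterior(draws)).iloc[0] == "neutral"

    def test_threshold_validation(self, small_fit):
        with pytest.raises(ValueError):
            classify_features(small_fit[0], threshold=0.4)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_count(self, seed):
        rng = np.random.default_rng(seed)
        draws = rng.normal(rng.normal(size=5), 1.0, size=(30, 5))
        labels = classify_features(_posterior(draws))
        for j in range(5):
            pos = (draws[:, j] > 0).sum() / 30
            neg = (draws[:, j] < 0).sum() / 30
            want = ("case-associated" if pos >= 0.7
                    else "control-associated" if neg >= 0.7 else "neutral")
            assert labels.iloc[j] == want


class TestConsensus:
    def _labels(self, *cols):
        return {f"s{i}": pd.Series(c, index=["F0"]) for i, c in enumerate(cols)}

    def test_two_study_rule(self):
        r = consensus_classification(self._labels(*(["case-associated"] * 3 + ["neutral"] * 4)))
        assert r.consensus["F0"] == "case-associated"

    def test_single_study_insufficient(self):
        r = consensus_classification(self._labels("case-associated", "neutral", "neutral"))
        assert r.consensus["F0"] == "neutral"

    def test_conflict_flagged_neutral(self):
        r = consensus_classification(self._labels(*(["case-associated"] * 2
                                                    + ["control-associated"] * 2)))
        assert r.consensus["F0"] == "neutral"
        assert r.conflicts == ["F0"]


class TestBalances:
    def _table(self, counts):
        counts = np.asarray(counts)
        return FeatureTable(counts, [f"s{i}" for i in range(counts.shape[0])],
                            [f"F{j}" for j in range(counts.shape[1])])

    def test_identity_sets_zero(self):
        t = self._table([[5, 7, 2]])
        b = compute_balance(t, ["F0", "F1"], ["F0", "F1"])
        assert abs(b.values.iloc[0]) < 1e-12

    def test_hand_computed_value(self):
        t = self._table([[8, 2, 1, 1]])
        b = compute_balance(t, ["F0", "F1"], ["F2", "F3"])
        assert abs(b.values.iloc[0] - np.log(4.0)) < 1e-12

    def test_scale_invariance_without_zeros(self):
        t1 = self._table([[8, 2, 1, 1]])
        t2 = self._table([[80, 20, 10, 10]])
        b1 = compute_balance(t1, ["F0"], ["F3"]).values.iloc[0]
        b2 = compute_balance(t2, ["F0"], ["F3"]).values.iloc[0]
        assert abs(b1 - b2) < 1e-12

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            compute_balance(self._table([[1, 2]]), [], ["F0"])

    def test_unknown_feature_named(self):
        with pytest.raises(ValueError, match="ghost"):
            compute_balance(self._table([[1, 2]]), ["ghost"], ["F0"])

    def test_pair_differences_and_fraction(self):
        t = self._table([[8, 1], [2, 4]])
        b = compute_balance(t, ["F0"], ["F1"])
        pairs = MatchedPairs(pairs=[(0, "s0", "s1")])
        diffs = pair_balance_differences(b, pairs)
        expect = (np.log(8) - np.log(1)) - (np.log(2) - np.log(4))
        assert abs(diffs["difference"].iloc[0] - expect) < 1e-12
        assert diffs.attrs["fraction_positive"] == 1.0

    def test_missing_balance_named(self):
        t = self._table([[8, 1]])
        b = compute_balance(t, ["F0"], ["F1"])
        with pytest.raises(ValueError, match="pair 0"):
            pair_balance_differences(b, MatchedPairs(pairs=[(0, "s0", "missing")]))


class TestSignificance:
    def test_partition(self):
        rng = np.random.default_rng(0)
        draws = np.column_stack([
            rng.uniform(0.5, 1.5, 40),        # increased
            rng.normal(0.0, 0.5, 40),         # stable
            rng.normal(0.0, 10.0, 40),        # uncertain (sd gate)
            -rng.uniform(0.5, 1.5, 40),       # decreased
        ])
        calls = significance_calls(_posterior(draws))
        assert calls.tolist() == ["increased", "stable", "uncertain", "decreased"]

    def test_every_feature_exactly_one_status(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(rng.normal(0, 2, 30), rng.uniform(0.1, 5, 30), size=(100, 30))
        calls = significance_calls(_posterior(draws))
        assert calls.isin(["increased", "decreased", "stable", "uncertain"]).all()


class TestEffectSize:
    def test_hand_computed(self):
        r = effect_size_and_p(np.array([[3.0, 0.0], [1.0, 0.0]]))
        assert r.radius == 1.0
        assert r.effect_size == 2.0
        assert r.p_bound == 0.5  # origin outside sphere, m=2

    def test_degenerate_identical_draws(self):
        r = effect_size_and_p(np.tile([2.0, 1.0], (5, 1)))
        assert np.isinf(r.effect_size) and r.degenerate

    def test_hundred_draw_bound(self):
        rng = np.random.default_rng(0)
        draws = np.array([5.0, 0.0]) + 0.1 * rng.standard_normal((100, 2))
        r = effect_size_and_p(draws)
        assert r.effect_size > 1
        assert r.p_bound == pytest.approx(0.01)

    def test_origin_inside_sphere_not_significant(self):
        rng = np.random.default_rng(1)
        r = effect_size_and_p(rng.standard_normal((100, 3)))
        assert r.effect_size < 1 and r.p_bound == 1.0

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            effect_size_and_p(np.array([[1.0]]))

    @given(st.integers(0, 2**31 - 1))
    def test_e_above_one_iff_origin_outside_sphere(self, seed):
        rng = np.random.default_rng(seed)
        draws = rng.normal(rng.normal(0, 2, 3), 1.0, size=(25, 3))
        r = effect_size_and_p(draws)
        dist_origin = np.linalg.norm(r.mu)
        outside = dist_origin > r.radius
        assert (r.effect_size > 1) == outside


class TestCLR:
    def _pairs(self):
        return MatchedPairs(pairs=[(0, "case0", "ctrl0")])

    def test_identical_samples_zero_row(self):
        t = FeatureTable(np.array([[4, 6, 2], [4, 6, 2]]), ["case0", "ctrl0"],
                         ["F0", "F1", "F2"])
        out = clr_pair_differences(t, self._pairs())
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_matches_independent_clr(self):
        from skbio.stats.composition import clr

        counts = np.array([[4, 1, 7], [1, 4, 3]])
        t = FeatureTable(counts, ["case0", "ctrl0"], ["F0", "F1", "F2"])
        out = clr_pair_differences(t, self._pairs())
        props = counts / counts.sum(axis=1, keepdims=True)
        expect = clr(props[0]) - clr(props[1])
        np.testing.assert_allclose(out.to_numpy()[0], expect, atol=1e-10)

    def test_rows_sum_to_zero(self, small_cohort):
        table, _, _, pairs = small_cohort
        out = clr_pair_differences(table, pairs)
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_all_zero_feature_excluded(self):
        t = FeatureTable(np.array([[4, 0, 7], [1, 0, 3]]), ["case0", "ctrl0"],
                         ["F0", "Fz", "F2"])
        with pytest.warns(UserWarning, match="Fz"):
            out = clr_pair_differences(t, self._pairs())
        assert list(out.columns) == ["F0", "F2"]
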