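"""The negative-binomial matched model: densities, gradients, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from matchrank.model import (
    ModelInput,
    _FeaturePosterior,
    build_model_input,
    compute_diagnostics,
    fit_matched_model,
    joint_log_density,
    nb_log_pmf,
)


@pytest.fixture(scope="module")
def model_input(small_cohort):
    table, metadata, truth, pairs = small_cohort
    return build_model_input(table, pairs, metadata)


def _params(mi, **over):
    base = {
        "D": 0.3, "C": np.full(mi.n_pairs, -2.0), "C_mu": -2.0, "C_sigma": 1.0,
        "a0": np.ones(mi.n_cohorts), "a1": np.full(mi.n_cohorts, 10.0),
        "beta_control": -9.0, "beta_case": -9.1, "beta_mu": -9.0, "beta_sigma": 0.1,
    }
    base.update(over)
    return base


class TestBuildModelInput:
    def test_shapes_and_offsets(self, small_cohort, model_input):
        table, metadata, _, pairs = small_cohort
        mi = model_input
        assert mi.counts.shape == (2 * len(pairs), table.d)
        assert mi.n_pairs == len(pairs)
        totals = mi.counts.sum(axis=1)
        np.testing.assert_allclose(mi.log_depth, np.log(totals))

    def test_each_pair_one_case_one_control(self, model_input):
        mi = model_input
        for k in range(mi.n_pairs):
            assert mi.case_indicator[mi.pair_index == k].sum() == 1

    def test_missing_sample_named(self, small_cohort):
        from matchrank.matching import MatchedPairs

        table, metadata, _, pairs = small_cohort
        bad = MatchedPairs(pairs=[(0, "ghost", pairs.pairs[0][2])])
        with pytest.raises(ValueError, match="ghost"):
            build_model_input(table, bad, metadata)

    def test_invariant_pair_structure_enforced(self, model_input):
        mi = model_input
        with pytest.raises(ValueError, match="pair 0"):
            ModelInput(mi.counts, mi.log_depth, np.zeros_like(mi.pair_index),
                       mi.case_indicator, mi.cohort_index, mi.sample_ids, mi.feature_ids)


class TestDensity:
    def test_nb_pmf_matches_gamma_poisson_mixture(self):
        # independent oracle: numerically integrate Poisson(y | lam*g) over
        # g ~ Gamma(1/alpha, alpha)
        y, lam, alpha = 5, 2.0, 0.5
        from scipy.integrate import quad

        def integrand(g):
            return stats.poisson.pmf(y, lam * g) * stats.gamma.pdf(g, 1 / alpha, scale=alpha)

        expected, _ = quad(integrand, 0, 60, limit=200)
        assert abs(np.exp(nb_log_pmf(y, lam, alpha)) - expected) < 1e-8

    def test_nb_pmf_matches_scipy_nbinom(self):
        y = np.arange(0, 30)
        lam, alpha = 4.0, 0.7
        r = 1 / alpha
        ref = stats.nbinom.logpmf(y, r, r / (r + lam))
        np.testing.assert_allclose(nb_log_pmf(y, lam, alpha), ref, atol=1e-10)

    def test_poisson_limit(self):
        # y=0, lam=1: Poisson log-pmf is -1
        assert abs(nb_log_pmf(0, 1.0, 1e-6) - (-1.0)) < 1e-3

    def test_offset_identity(self, model_input):
        mi = model_input
        p1 = _params(mi)
        lp1 = joint_log_density(p1, mi, 0)
        c = 0.37
        shifted = ModelInput(mi.counts, mi.log_depth + c, mi.pair_index,
                             mi.case_indicator, mi.cohort_index, mi.sample_ids,
                             mi.feature_ids)
        p2 = _params(mi, C=p1["C"] - c, C_mu=p1["C_mu"] - c)
        lp2 = joint_log_density(p2, shifted, 0)
        # likelihood term identical; only the C prior shifts
        prior_diff = (
            -0.5 * ((p2["C_mu"] - 1 / mi.d) / 3) ** 2
            + 0.5 * ((p1["C_mu"] - 1 / mi.d) / 3) ** 2
        )
        assert abs((lp2 - lp1) - prior_diff) < 1e-8

    def test_nonfinite_parameter_rejected(self, model_input):
        with pytest.raises(ValueError, match="non-finite"):
            joint_log_density(_params(model_input, D=np.nan), model_input, 0)

    @pytest.mark.parametrize("pooled", [False, True])
    def test_gradient_matches_finite_differences(self, model_input, pooled):
        mi = model_input
        sub = ModelInput(mi.counts[:, [1]], mi.log_depth, mi.pair_index,
                         mi.case_indicator, mi.cohort_index, mi.sample_ids,
                         [mi.feature_ids[1]])
        post = _FeaturePosterior(sub, pooled_baseline=pooled)
        theta = post.initial_positions(1, np.random.default_rng(0)).reshape(1, -1)
        _, grad = post.logp_and_grad(theta)
        for i in range(theta.shape[1]):
            hi, lo_ = theta.copy(), theta.copy()
            hi[0, i] += 1e-6
            lo_[0, i] -= 1e-6
            fd = (post.logp(hi)[0] - post.logp(lo_)[0]) / 2e-6
            assert abs(fd - grad[0, i]) <= 1e-4 * max(1.0, abs(grad[0, i]))


class TestDiagnostics:
    def test_iid_chains_converged(self):
        rng = np.random.default_rng(0)
        d = compute_diagnostics(rng.standard_normal((4, 1000, 1)))
        assert d.rhat[0] < 1.01
        assert abs(d.ess[0] - 4000) < 0.2 * 4000

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((2, 500, 1))
        draws[0] -= 5.0
        draws[1] += 5.0
        assert compute_diagnostics(draws).rhat[0] > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            compute_diagnostics(np.zeros((1, 100, 2)))

    def test_ess_capped_at_draw_count(self):
        rng = np.random.default_rng(2)
        d = compute_diagnostics(rng.standard_normal((4, 250, 3)))
        assert (d.ess <= 1000).all()


class TestFitBehavior:
    def test_all_zero_feature_skipped(self, small_cohort):
        table, metadata, _, pairs = small_cohort
        counts = table.counts.copy()
        counts[:, 3] = 0
        from matchrank.io import FeatureTable

        t = FeatureTable(counts, table.sample_ids, table.feature_ids)
        mi = build_model_input(t, pairs, metadata)
        with pytest.warns(UserWarning, match="all-zero"):
            post = fit_matched_model(mi, {"chains": 2, "warmup": 150, "draws": 150, "seed": 1})
        assert table.feature_ids[3] not in post.feature_ids
        assert post.skipped_features == [table.feature_ids[3]]

    def test_summary_consistent_with_draws(self, small_fit):
        post, _ = small_fit
        np.testing.assert_allclose(post.summary["mean"], post.draws.mean(axis=0), atol=1e-10)
        q = np.quantile(post.draws, [0.05, 0.5, 0.95], axis=0)
        assert (post.summary["q05"] <= post.summary["q50"] + 1e-12).all()
        assert (post.summary["q50"] <= post.summary["q95"] + 1e-12).all()
        np.testing.assert_allclose(post.summary["q05"], q[0], atol=1e-10)

    def test_deterministic_given_seed(self, small_cohort):
        table, metadata, _, pairs = small_cohort
        mi = build_model_input(table, pairs, metadata)
        cfg = {"chains": 2, "warmup": 150, "draws": 150, "seed": 11}
        a = fit_matched_model(mi, cfg)
        b = fit_matched_model(mi, cfg)
        np.testing.assert_array_equal(a.chain_draws, b.chain_draws)

    def test_single_pair_posterior_wider_than_full(self, small_cohort, small_fit):
        table, metadata, _, pairs = small_cohort
        from matchrank.matching import MatchedPairs

        one = MatchedPairs(pairs=pairs.pairs[:1])
        mi = build_model_input(table, one, metadata)
        post1 = fit_matched_model(mi, {"chains": 2, "warmup": 300, "draws": 300, "seed": 3})
        post_full, _ = small_fit
        assert post1.summary["sd"].median() > post_full.summary["sd"].median()

    def test_estimator_get_params_round_trip(self):
        from matchrank.model import MatchedDifferentialModel

        est = MatchedDifferentialModel(chains=2, draws=123)
        params = est.get_params()
        assert params["draws"] == 123
        est.set_params(draws=55)
        assert est.draws == 55
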