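import numpy as np
import pandas as pd
import pytest
import scipy.stats

from groupbandit import (
    DataError,
    DesignError,
    SimpleParams,
    MemberProfile,
    fit_map,
    kruskal_wallis,
    pairwise_wilcoxon_bonferroni,
    performance,
    poisson_regression,
    positivity_bias_test,
    simulate_agent_session,
    simulate_group_session,
    within_group_contrast,
)
from ._oracles import exact_ranksum_p


class TestPerformance:
    def test_counts_rewarded_trials(self):
        assert performance(np.ones(100, dtype=int)) == 100
        assert performance(np.zeros(100, dtype=int)) == 0
        assert performance(np.tile([1, 0], 50)) == 50

    def test_performance_plus_failures_is_total(self, example_session):
        n_fail = int((example_session.rewards == 0).sum())
        assert performance(example_session) + n_fail == example_session.n_trials

    def test_non_binary_rewards_rejected(self):
        with pytest.raises(DataError):
            performance(np.array([0, 1, 7]))


class TestKruskalWallis:
    def test_identical_samples_are_null(self):
        s = [1.0, 2.0, 3.0, 4.0]
        res = kruskal_wallis({"a": s, "b": s, "c": s})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw > 0.99

    def test_three_groups_have_two_df(self):
        res = kruskal_wallis({"i": [1, 2], "d": [3, 4], "t": [5, 6]})
        assert res.df == 2

    def test_matches_hand_rank_computation(self):
        groups = {"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0]}
        n = 6
        rank_sums = {"a": 1 + 2, "b": 3 + 4, "c": 5 + 6}
        h = 12.0 / (n * (n + 1)) * sum(rs**2 / 2 for rs in rank_sums.values()) - 3 * (n + 1)
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(h, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            kruskal_wallis({"a": [1, 2], "b": []})


class TestPairwiseWilcoxon:
    def test_identical_groups_fully_adjusted(self):
        s = [1.0, 2.0, 3.0]
        for res in pairwise_wilcoxon_bonferroni({"a": s, "b": s, "c": s}):
            assert res.p_adjusted == 1.0

    def test_bonferroni_multiplies_by_pair_count(self):
        rng = np.random.default_rng(0)
        samples = {k: rng.normal(i, 1, 12) for i, k in enumerate("abc")}
        results = pairwise_wilcoxon_bonferroni(samples)
        assert len(results) == 3
        for res in results:
            assert res.p_adjusted == pytest.approx(min(1.0, 3 * res.p_raw))
            assert res.p_adjusted >= res.p_raw

    def test_small_sample_p_matches_exact_enumeration(self):
        x = [1.2, 3.4, 5.1, 7.9]
        y = [2.2, 4.0, 9.5, 11.0, 12.5]
        res = pairwise_wilcoxon_bonferroni({"x": x, "y": y})[0]
        assert res.p_raw == pytest.approx(exact_ranksum_p(x, y), abs=1e-10)


class TestWithinGroupContrast:
    def test_identical_vectors_are_null(self):
        v = [1.0, 2.0, 3.0, 4.0]
        res = within_group_contrast(v, v)
        assert res.p_raw > 0.99
        assert res.direction is None

    def test_shifted_aggregate_detected_with_direction(self, rng):
        g = rng.normal(0, 1, 60)
        res = within_group_contrast(g, g + 2.0)
        assert res.p_raw < 1e-6
        assert res.df == 1
        assert res.direction == "aggregate_higher"

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            within_group_contrast([1, 2, 3], [1, 2])

    def test_paired_variant_on_zero_differences(self):
        v = [1.0, 2.0, 3.0]
        res = within_group_contrast(v, v, paired=True)
        assert res.p_raw == 1.0 and res.degenerate

    def test_incoherent_dyads_fit_below_member_average_beta(self):
        # Fully incoherent dyads fragment each member's learning stream, so
        # the group-level softmax looks flatter than its members' solo
        # sessions: the fitted group beta falls below the member average.
        rng = np.random.default_rng(11)
        group_beta, member_mean = [], []
        for i in range(120):
            pa = SimpleParams(float(rng.beta(2, 2)), float(rng.gamma(2, 2.5)))
            pb = SimpleParams(float(rng.beta(2, 2)), float(rng.gamma(2, 2.5)))
            members = [MemberProfile("a", pa), MemberProfile("b", pb)]
            g = simulate_group_session(members, coherence=0.0, rng=rng)
            ia = simulate_agent_session(pa, rng=rng)
            ib = simulate_agent_session(pb, rng=rng)
            group_beta.append(fit_map(g, "simple", n_restarts=4, rng=i).map_params.beta)
            member_mean.append(
                (
                    fit_map(ia, "simple", n_restarts=4, rng=1000 + i).map_params.beta
                    + fit_map(ib, "simple", n_restarts=4, rng=2000 + i).map_params.beta
                )
                / 2.0
            )
        res = within_group_contrast(group_beta, member_mean)
        assert res.direction == "aggregate_higher"
        assert res.p_raw < 0.01


class TestPositivityBias:
    def test_null_sample_rarely_significant(self):
        rng = np.random.default_rng(1)
        hits = sum(
            positivity_bias_test(rng.normal(0, 0.3, 200)).p_raw < 0.05
            for _ in range(100)
        )
        assert hits <= 10  # nominal 5% false-positive rate

    def test_shifted_sample_detected_as_positive(self, rng):
        res = positivity_bias_test(rng.uniform(0.05, 0.4, 50))
        assert res.p_raw < 1e-6 and res.direction == "positive"

    def test_all_zero_vector_is_degenerate(self):
        res = positivity_bias_test(np.zeros(20))
        assert res.p_raw == 1.0 and res.degenerate

    def test_empty_vector_rejected(self):
        with pytest.raises(DataError):
            positivity_bias_test([])


class TestPoissonRegression:
    def test_intercept_only_equals_sample_mean(self, rng):
        y = rng.poisson(50, 200)
        frame = pd.DataFrame({"performance": y, "size": np.ones(200)})
        table = poisson_regression(frame, spec="intercept")
        assert table.coef["const"] == pytest.approx(y.mean(), abs=1e-9)

    def test_matches_statsmodels_identity_poisson(self, rng):
        statsmodels = pytest.importorskip("statsmodels.api")
        sizes = np.repeat([1, 2, 3], 40)
        mu = 54.0 - 7.0 * sizes + 1.8 * sizes**2
        y = rng.poisson(mu)
        frame = pd.DataFrame({"performance": y, "size": sizes})
        ours = poisson_regression(frame, spec="quadratic")
        X = np.column_stack([np.ones_like(sizes), sizes, sizes**2])
        ref = statsmodels.GLM(
            y,
            X,
            family=statsmodels.families.Poisson(statsmodels.families.links.Identity()),
        ).fit(start_params=ours.coef.to_numpy())
        assert np.allclose(ours.coef.to_numpy(), ref.params, atol=1e-5)
        assert np.allclose(ours.params["se"].to_numpy(), ref.bse, atol=1e-4)
        assert ours.aic == pytest.approx(ref.aic, abs=1e-3)

    def test_aic_definition_on_toy_fit(self):
        frame = pd.DataFrame(
            {"performance": [3, 5, 2, 8, 7, 4, 6, 5, 3, 7], "size": np.ones(10)}
        )
        table = poisson_regression(frame, spec="intercept")
        assert table.aic == pytest.approx(-2 * table.log_likelihood + 2 * 1, abs=1e-12)

    def test_dummy_specs_have_expected_terms(self, rng):
        sizes = np.repeat([1, 2, 3], 30)
        y = rng.poisson(50, sizes.size)
        frame = pd.DataFrame({"performance": y, "size": sizes})
        t1 = poisson_regression(frame, spec="dummies1")
        t2 = poisson_regression(frame, spec="dummies2")
        assert list(t1.params.index) == ["const", "individual", "triad"]
        assert list(t2.params.index) == ["const", "dyad", "triad"]

    def test_invalid_inputs_rejected(self, rng):
        y = rng.poisson(50, 30)
        frame = pd.DataFrame({"performance": y, "size": np.ones(30)})
        with pytest.raises(DesignError):
            poisson_regression(frame, spec="cubic")
        with pytest.raises(DataError):
            bad = frame.assign(performance=frame["performance"] + 0.5)
            poisson_regression(bad, spec="intercept")
        with pytest.raises(DesignError):  # size duplicated -> rank deficient
            poisson_regression(frame.assign(size=2.0), spec="quadratic",
                               covariates=["size"])
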