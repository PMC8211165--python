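import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from groupbandit import (
    AsymParams,
    DesignError,
    GroupDesign,
    MemberProfile,
    PopulationSpec,
    SimpleParams,
    fit_map,
    generate_dataset,
    simulate_agent_session,
    simulate_group_session,
)


def _profiles(params_list):
    return [MemberProfile(f"m{i}", p) for i, p in enumerate(params_list)]


class TestAgentSimulation:
    def test_default_session_has_100_trials(self, example_session):
        assert example_session.n_trials == 100
        assert example_session.size == 1

    def test_random_policy_earns_half_the_trials(self):
        rng = np.random.default_rng(3)
        perfs = [
            simulate_agent_session(SimpleParams(0.5, 0.0), rng=rng).performance
            for _ in range(1000)
        ]
        # a uniform policy wins (0.7 + 0.3)/2 of trials in expectation
        se = np.std(perfs, ddof=1) / np.sqrt(len(perfs))
        assert abs(np.mean(perfs) - 50.0) < 3 * se

    def test_learners_beat_random_agents(self):
        rng = np.random.default_rng(4)
        learner = [
            simulate_agent_session(SimpleParams(0.6, 6.0), rng=rng).performance
            for _ in range(500)
        ]
        random_agent = [
            simulate_agent_session(SimpleParams(0.6, 0.0), rng=rng).performance
            for _ in range(500)
        ]
        assert np.mean(learner) > np.mean(random_agent)

    def test_asymmetric_generator_supported(self):
        s = simulate_agent_session(AsymParams(0.6, 0.2, 5.0, 0.1), rng=8)
        assert s.n_trials == 100
        assert s.ground_truth["model_id"] == "asymmetric"


class TestGroupSimulation:
    @pytest.mark.parametrize("coherence", [0.0, 0.3, 1.0])
    def test_singleton_group_equals_solo_agent(self, coherence):
        params = SimpleParams(0.55, 4.0)
        solo = simulate_agent_session(params, rng=777)
        group = simulate_group_session(
            [MemberProfile("solo.m1", params)], coherence=coherence, rng=777
        )
        assert np.array_equal(solo.choices, group.choices)
        assert np.array_equal(solo.rewards, group.rewards)

    def test_identical_members_with_shared_updates_match_solo_distribution(self):
        # With a shared learning stream, identical members hold identical
        # Q-values, so any controller produces the solo agent's policy.
        params = SimpleParams(0.6, 5.0)
        rng = np.random.default_rng(9)
        dyad = [
            simulate_group_session(
                _profiles([params, params]), coherence=0.0, rng=rng,
                shared_updates=True,
            ).performance
            for _ in range(300)
        ]
        solo = [
            simulate_agent_session(params, rng=rng).performance for _ in range(300)
        ]
        p = mannwhitneyu(dyad, solo, alternative="two-sided").pvalue
        assert p > 0.01  # identical controllers: no detectable difference

    def test_fragmented_learning_costs_identical_members_performance(self):
        # Under the default incoherence model each member trains on only
        # their own turns, so even clones underperform a solo agent.
        params = SimpleParams(0.6, 5.0)
        rng = np.random.default_rng(9)
        dyad = [
            simulate_group_session(
                _profiles([params, params]), coherence=0.0, rng=rng
            ).performance
            for _ in range(300)
        ]
        solo = [
            simulate_agent_session(params, rng=rng).performance for _ in range(300)
        ]
        assert np.mean(dyad) < np.mean(solo)

    def test_incoherent_dyad_beta_fit_lies_between_member_betas(self):
        rng = np.random.default_rng(11)
        fitted = []
        for i in range(200):
            members = _profiles([SimpleParams(0.5, 1.0), SimpleParams(0.5, 8.0)])
            s = simulate_group_session(members, coherence=0.0, rng=rng)
            fitted.append(fit_map(s, "simple", n_restarts=5, rng=1000 + i).map_params.beta)
        assert 1.0 < np.mean(fitted) < 8.0

    def test_fitted_group_beta_non_decreasing_in_coherence(self):
        rng = np.random.default_rng(13)
        means = []
        for c in (0.0, 0.5, 1.0):
            fitted = []
            for i in range(200):
                pa = SimpleParams(float(rng.beta(2, 2)), float(rng.gamma(2, 2.5)))
                pb = SimpleParams(float(rng.beta(2, 2)), float(rng.gamma(2, 2.5)))
                s = simulate_group_session(_profiles([pa, pb]), coherence=c, rng=rng)
                fitted.append(
                    fit_map(s, "simple", n_restarts=4, rng=5000 + i).map_params.beta
                )
            means.append(np.mean(fitted))
        assert means[0] <= means[1] <= means[2]

    def test_group_errors(self):
        with pytest.raises(DesignError):
            simulate_group_session([], coherence=0.5, rng=1)
        with pytest.raises(DesignError):
            simulate_group_session(
                _profiles([SimpleParams(0.5, 1.0)]), coherence=1.5, rng=1
            )


class TestGenerateDataset:
    def test_study_mimicking_counts(self):
        design = GroupDesign(seed=21)
        dataset = generate_dataset(design)
        sizes = np.array([s.size for s in dataset.sessions])
        assert (sizes == 1).sum() == 322
        assert (sizes == 2).sum() == 138
        assert (sizes == 3).sum() == 108

    def test_empty_design_yields_empty_dataset(self):
        design = GroupDesign(n_individual_sessions=0, n_dyads=0, n_triads=0, seed=1)
        dataset = generate_dataset(design)
        assert len(dataset) == 0
        assert dataset.trials_frame().empty

    def test_same_seed_reproduces_tables_byte_identically(self):
        design = dict(n_individual_sessions=12, n_dyads=6, n_triads=5, seed=77)
        a = generate_dataset(GroupDesign(**design))
        b = generate_dataset(GroupDesign(**design))
        assert a.trials_frame().to_csv() == b.trials_frame().to_csv()
        assert a.ground_truth_frame().to_csv() == b.ground_truth_frame().to_csv()

    def test_membership_overlap_links_groups_to_solo_sessions(self):
        design = GroupDesign(n_individual_sessions=20, n_dyads=10, n_triads=8, seed=3)
        dataset = generate_dataset(design)
        solo_members = {
            s.member_ids[0] for s in dataset.sessions if s.size == 1
        }
        for s in dataset.sessions:
            if s.size >= 2:
                assert set(s.member_ids) <= solo_members

    def test_ground_truth_and_units_consistent(self):
        design = GroupDesign(n_individual_sessions=8, n_dyads=4, n_triads=3, seed=5)
        dataset = generate_dataset(design)
        units = dataset.units_frame()
        gt = dataset.ground_truth_frame()
        assert units["unit_id"].is_unique
        assert set(gt["unit_id"]) == set(units["unit_id"])
        # one ground-truth row per member of each unit
        assert gt.groupby("unit_id").size().to_dict() == {
            s.unit_id: s.size for s in dataset.sessions
        }

    def test_overlap_requires_solo_pool(self):
        with pytest.raises(DesignError):
            GroupDesign(n_individual_sessions=0, n_dyads=3, n_triads=0, seed=1)

    def test_population_bounds_respected(self):
        pop = PopulationSpec()
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = pop.draw("asymmetric", rng)
            assert 0 < p.alpha_plus <= 1 and 0 < p.alpha_minus <= 1 and p.beta >= 0
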