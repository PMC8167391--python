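"""Trial simulator: determinism, design bookkeeping, convergence of
empirical quantities to their analytic counterparts."""

import numpy as np
import pandas as pd
import pytest

from testtreat import (
    DegenerateAnalysisError,
    DiseasePopulation,
    JointOutcomeModel,
    PairedTestModel,
    ScenarioModel,
    TestAccuracy,
    chi2_two_proportions,
    discordance_fraction,
    estimate_power,
    run_classical,
    run_discordant,
    run_random_disclosure,
    run_single_test_disclosure,
    simulate_cohort,
    theta_unpaired,
)


class TestCohort:
    def test_same_seed_gives_identical_cohorts(self, worked_scenario):
        c1 = simulate_cohort(worked_scenario, 500, 42)
        c2 = simulate_cohort(worked_scenario, 500, 42)
        pd.testing.assert_frame_equal(c1, c2)

    def test_zero_prevalence_yields_no_disease(self, worked_tests):
        scenario = ScenarioModel(
            population=DiseasePopulation(0.0),
            tests=worked_tests,
            outcomes=JointOutcomeModel.constant(0.5),
        )
        cohort = simulate_cohort(scenario, 2000, 1)
        assert (cohort["d"] == 0).all()

    def test_empirical_discordance_matches_analytic(self, worked_scenario):
        n = 100_000
        cohort = simulate_cohort(worked_scenario, n, 7)
        frac = discordance_fraction(worked_scenario.tests, worked_scenario.population)
        emp = (cohort["r_a"] != cohort["r_b"]).mean()
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(emp - frac) < 3 * se

    def test_empirical_marginals_match_accuracy(self, worked_scenario):
        cohort = simulate_cohort(worked_scenario, 100_000, 3)
        diseased = cohort[cohort["d"] == 1]
        assert diseased["r_a"].mean() == pytest.approx(0.9, abs=0.01)
        assert diseased["r_b"].mean() == pytest.approx(0.7, abs=0.01)


class TestClassical:
    def test_printed_dysphagia_table_is_non_significant(self):
        _, p, est = chi2_two_proportions(14, 76, 6, 50)
        assert p > 0.05
        assert est == pytest.approx(0.064, abs=5e-4)

    def test_determinism(self, worked_scenario):
        cohort = simulate_cohort(worked_scenario, 400, 5)
        t1 = run_classical(worked_scenario, cohort, 9)
        t2 = run_classical(worked_scenario, cohort, 9)
        pd.testing.assert_frame_equal(t1.dataset, t2.dataset)
        assert t1.p_value == t2.p_value

    def test_management_follows_link_rule(self, worked_scenario):
        cohort = simulate_cohort(worked_scenario, 400, 5)
        trial = run_classical(worked_scenario, cohort, 9)
        df = trial.dataset
        followed_r = np.where(df["followed_test"] == "A", df["r_a"], df["r_b"])
        expected = np.where(followed_r == 1, "I", "II")
        assert (df["management"] == expected).all()
        # only the assigned test's result is observed
        assert (df["r_a_observed"] ^ df["r_b_observed"]).all()

    def test_empirical_thetas_converge_to_analytic(self, worked_scenario):
        n = 100_000
        cohort = simulate_cohort(worked_scenario, n, 21)
        trial = run_classical(worked_scenario, cohort, 22)
        df = trial.dataset
        for arm, tau in (("A", "A"), ("B", "B")):
            sub = df[df["arm"] == arm]
            theta = theta_unpaired(worked_scenario, tau)
            se = np.sqrt(theta * (1 - theta) / len(sub))
            assert abs(sub["y"].mean() - theta) < 3 * se


class TestDiscordant:
    def test_analysis_restricted_to_discordant(self, worked_scenario):
        cohort = simulate_cohort(worked_scenario, 1000, 5)
        trial = run_discordant(worked_scenario, cohort, 6)
        df = trial.dataset
        disc = df["r_a"] != df["r_b"]
        assert trial.n_analyzed == int(disc.sum())
        assert (df.loc[~disc, "arm"] == "concordant").all()
        assert (df.loc[~disc, "followed_test"] == "none").all()

    def test_no_discordance_is_degenerate(self, worked_population):
        tests = PairedTestModel(
            TestAccuracy(0.8, 0.9), TestAccuracy(0.8, 0.9), cov_diseased=0.16, cov_nondiseased=0.09
        )
        scenario = ScenarioModel(
            population=worked_population, tests=tests, outcomes=JointOutcomeModel.constant(0.5)
        )
        cohort = simulate_cohort(scenario, 200, 1)
        with pytest.raises(DegenerateAnalysisError):
            run_discordant(scenario, cohort, 2)

    def test_mean_estimate_tracks_delta_disc(self, worked_scenario):
        # the discordant analysis estimates Delta^disc = Delta / P(disc)
        # hand value: moves 0.2*(0.081-0.021) + 0.1*(0.056-0.126) = 0.005
        summary_delta_disc = 0.005 / 0.284
        ests = []
        rng = np.random.default_rng(31)
        for _ in range(300):
            cohort = simulate_cohort(worked_scenario, 2000, rng)
            ests.append(run_discordant(worked_scenario, cohort, rng).estimate)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - summary_delta_disc) < 4 * se


class TestRandomDisclosure:
    def test_both_results_exist_but_one_is_revealed(self, worked_scenario):
        cohort = simulate_cohort(worked_scenario, 500, 2)
        trial = run_random_disclosure(worked_scenario, cohort, 3)
        df = trial.dataset
        assert (df["r_a"] >= 0).all() and (df["r_b"] >= 0).all()
        assert (df["r_a_observed"] ^ df["r_b_observed"]).all()
        assert trial.n_analyzed == len(df)

    def test_discordant_subgroup_analysis_counts(self, worked_scenario):
        cohort = simulate_cohort(worked_scenario, 500, 2)
        trial = run_random_disclosure(worked_scenario, cohort, 3, analysis="discordant_subgroup")
        assert trial.n_analyzed == int((cohort["r_a"] != cohort["r_b"]).sum())


class TestSingleTestDisclosure:
    def test_non_disclosure_arm_never_gets_management_ii(self, worked_scenario):
        cohort = simulate_cohort(worked_scenario, 600, 4)
        trial = run_single_test_disclosure(worked_scenario, cohort, 5)
        df = trial.dataset
        nd = df[df["arm"] == "non_disclosure"]
        assert (nd["management"] == "I").sum() == len(nd)

    def test_disclosure_superior_when_management_ii_helps_negatives(
        self, worked_tests, worked_population
    ):
        # e(II | negative, non-diseased) > e(I | negative, non-diseased):
        # following the test spares healthy negatives the aggressive
        # management, so the disclosure arm has the better mean outcome
        scenario = ScenarioModel(
            population=worked_population,
            tests=worked_tests,
            outcomes=JointOutcomeModel.from_management_disease(
                {("I", 1): 0.7, ("II", 1): 0.7, ("I", 0): 0.6, ("II", 0): 0.95}
            ),
        )
        rng = np.random.default_rng(8)
        ests = [
            run_single_test_disclosure(scenario, simulate_cohort(scenario, 800, rng), rng).estimate
            for _ in range(100)
        ]
        assert np.mean(ests) > 0


class TestEstimatePower:
    def test_null_scenario_rejects_at_alpha(self, worked_population):
        tests = PairedTestModel(TestAccuracy(0.8, 0.9), TestAccuracy(0.8, 0.9))
        scenario = ScenarioModel(
            population=worked_population,
            tests=tests,
            outcomes=JointOutcomeModel.from_management_disease(
                {("I", 1): 0.4, ("II", 1): 0.4, ("I", 0): 0.25, ("II", 0): 0.25}
            ),
        )
        summary = estimate_power(scenario, "classical", 600, n_reps=2000, seed=12)
        assert abs(summary.rejection_rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_single_replicate_rate_is_binary(self, worked_scenario):
        summary = estimate_power(worked_scenario, "classical", 100, n_reps=1, seed=0)
        assert summary.rejection_rate in (0.0, 1.0)
        assert summary.mc_standard_error == 0.0

    def test_seed_determinism(self, worked_scenario):
        s1 = estimate_power(worked_scenario, "classical", 200, n_reps=200, seed=5)
        s2 = estimate_power(worked_scenario, "classical", 200, n_reps=200, seed=5)
        assert s1 == s2
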