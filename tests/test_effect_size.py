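"""Effect-size derivations: unpaired/paired expansions, moves,
discordance, and their consistency identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from testtreat import (
    DiseasePopulation,
    JointOutcomeModel,
    MoveEffects,
    PairedTestModel,
    ScenarioModel,
    TestAccuracy,
    UndefinedEffectError,
    delta_discordant,
    delta_paired,
    delta_paired_from_joint,
    discordance_fraction,
    frechet_bounds,
    move_probabilities,
    summarize_effects,
    theta_discordant,
    theta_unpaired,
)

from conftest import brute_theta, brute_theta_discordant, random_scenario


class TestThetaUnpaired:
    def test_perfect_test_two_cell_sum(self):
        # prevalence 0.2, perfect test: theta = 0.2 * e(I|+) + 0.8 * e(II|-)
        scenario = ScenarioModel(
            population=DiseasePopulation(0.2),
            tests=PairedTestModel(TestAccuracy(1.0, 1.0), TestAccuracy(1.0, 1.0)),
            outcomes=JointOutcomeModel.from_management_disease(
                {("I", 1): 0.7, ("II", 1): 0.4, ("I", 0): 0.6, ("II", 0): 0.95}
            ),
        )
        assert theta_unpaired(scenario, "A") == pytest.approx(0.2 * 0.7 + 0.8 * 0.95)

    def test_constant_outcome_gives_constant_theta(self, worked_tests, worked_population):
        scenario = ScenarioModel(
            population=worked_population,
            tests=worked_tests,
            outcomes=JointOutcomeModel.constant(0.42),
        )
        assert theta_unpaired(scenario, "A") == pytest.approx(0.42)
        assert theta_unpaired(scenario, "B") == pytest.approx(0.42)

    def test_matches_eight_atom_enumeration(self, worked_scenario):
        for tau in ("A", "B"):
            assert theta_unpaired(worked_scenario, tau) == pytest.approx(
                brute_theta(worked_scenario, tau), abs=1e-12
            )

    def test_matches_enumeration_on_random_dependent_scenarios(self):
        rng = np.random.default_rng(20260921)
        for _ in range(25):
            scenario = random_scenario(rng)
            for tau in ("A", "B"):
                assert theta_unpaired(scenario, tau) == pytest.approx(
                    brute_theta(scenario, tau), abs=1e-10
                )


class TestMoveProbabilities:
    def test_worked_scenario_values(self, worked_tests, worked_population):
        p = move_probabilities(worked_tests, worked_population)
        assert p.p_fn_to_tp == pytest.approx(0.081)
        assert p.p_tp_to_fn == pytest.approx(0.021)
        assert p.p_tn_to_fp == pytest.approx(0.126)
        assert p.p_fp_to_tn == pytest.approx(0.056)

    def test_comonotone_identical_tests_have_no_moves(self, worked_population):
        tests = PairedTestModel(
            TestAccuracy(0.8, 0.9),
            TestAccuracy(0.8, 0.9),
            cov_diseased=0.8 * 0.2,
            cov_nondiseased=0.1 * 0.9,
        )
        p = move_probabilities(tests, worked_population)
        assert p.p_fn_to_tp == p.p_tp_to_fn == p.p_tn_to_fp == p.p_fp_to_tn == 0.0

    def test_zero_prevalence_kills_diseased_moves(self, worked_tests):
        p = move_probabilities(worked_tests, DiseasePopulation(0.0))
        assert p.p_fn_to_tp == 0.0 and p.p_tp_to_fn == 0.0
        assert p.p_tn_to_fp > 0.0


class TestDiscordance:
    def test_worked_fraction_is_sum_of_moves(self, worked_tests, worked_population):
        frac = discordance_fraction(worked_tests, worked_population)
        assert frac == pytest.approx(0.284)
        p = move_probabilities(worked_tests, worked_population)
        assert frac == pytest.approx(p.total, abs=1e-15)

    @given(cov_lo=st.floats(0.0, 1.0), cov_hi=st.floats(0.0, 1.0))
    def test_fraction_non_increasing_in_covariance(self, cov_lo, cov_hi):
        worked_population = DiseasePopulation(0.3)
        acc_a, acc_b = TestAccuracy(0.9, 0.8), TestAccuracy(0.7, 0.9)
        lo1, hi1 = frechet_bounds(0.9, 0.7)
        c1, c2 = sorted([lo1 + cov_lo * (hi1 - lo1), lo1 + cov_hi * (hi1 - lo1)])
        t_low = PairedTestModel(acc_a, acc_b, cov_diseased=c1)
        t_high = PairedTestModel(acc_a, acc_b, cov_diseased=c2)
        assert discordance_fraction(t_low, worked_population) >= discordance_fraction(
            t_high, worked_population
        ) - 1e-12

    def test_maximally_negative_dependence_maximizes_discordance(self, worked_population):
        acc_a, acc_b = TestAccuracy(0.9, 0.8), TestAccuracy(0.7, 0.9)
        lo_d, hi_d = frechet_bounds(0.9, 0.7)
        lo_n, hi_n = frechet_bounds(0.2, 0.1)
        at_min = PairedTestModel(acc_a, acc_b, cov_diseased=lo_d, cov_nondiseased=lo_n)
        frac_min = discordance_fraction(at_min, worked_population)
        rng = np.random.default_rng(7)
        for _ in range(50):
            tests = PairedTestModel(
                acc_a,
                acc_b,
                cov_diseased=rng.uniform(lo_d, hi_d),
                cov_nondiseased=rng.uniform(lo_n, hi_n),
            )
            assert discordance_fraction(tests, worked_population) <= frac_min + 1e-12


class TestDeltaPaired:
    def test_worked_four_term_sum(self, worked_tests, worked_population):
        moves = MoveEffects(delta_fp_to_tn=0.1, delta_fn_to_tp=0.2)
        delta = delta_paired(worked_tests, worked_population, moves)
        assert delta == pytest.approx(0.1 * 0.056 - 0.1 * 0.126 + 0.2 * 0.081 - 0.2 * 0.021)
        assert delta == pytest.approx(0.005)

    def test_no_discordance_means_no_effect(self, worked_population):
        tests = PairedTestModel(
            TestAccuracy(0.8, 0.9), TestAccuracy(0.8, 0.9), cov_diseased=0.16, cov_nondiseased=0.09
        )
        moves = MoveEffects(delta_fp_to_tn=0.3, delta_fn_to_tp=0.4)
        assert delta_paired(tests, worked_population, moves) == 0.0

    def test_symmetric_moves_cancel(self, worked_population):
        # identical marginals -> symmetric discordant probabilities within
        # each stratum; symmetric effects then cancel exactly
        tests = PairedTestModel(TestAccuracy(0.8, 0.9), TestAccuracy(0.8, 0.9))
        moves = MoveEffects(delta_fp_to_tn=0.25, delta_fn_to_tp=0.15)
        assert delta_paired(tests, worked_population, moves) == pytest.approx(0.0, abs=1e-15)

    def test_override_breaks_sign_symmetry(self):
        moves = MoveEffects(delta_fp_to_tn=0.1, delta_fn_to_tp=0.2, delta_tn_to_fp=-0.05)
        assert moves.tn_to_fp == -0.05
        assert moves.tp_to_fn == -0.2


class TestDeltaFromJoint:
    def test_no_prognostic_value_reduces_to_theta_difference(self, worked_scenario):
        assert delta_paired_from_joint(worked_scenario) == pytest.approx(
            theta_unpaired(worked_scenario, "A") - theta_unpaired(worked_scenario, "B"),
            abs=1e-12,
        )

    def test_constant_outcome_has_zero_effect(self, worked_tests, worked_population):
        scenario = ScenarioModel(
            population=worked_population,
            tests=worked_tests,
            outcomes=JointOutcomeModel.constant(0.6),
        )
        assert delta_paired_from_joint(scenario) == pytest.approx(0.0, abs=1e-15)

    def test_general_scenario_matches_atom_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            scenario = random_scenario(rng)
            expected = brute_theta(scenario, "A") - brute_theta(scenario, "B")
            assert delta_paired_from_joint(scenario) == pytest.approx(expected, abs=1e-10)


class TestDeltaDiscordant:
    def test_worked_division(self):
        assert delta_discordant(0.005, 0.284) == pytest.approx(0.005 / 0.284)

    def test_zero_effect_stays_zero(self):
        assert delta_discordant(0.0, 0.5) == 0.0

    def test_full_discordance_is_identity(self):
        assert delta_discordant(0.0123, 1.0) == pytest.approx(0.0123)

    def test_no_discordance_is_undefined(self):
        with pytest.raises(UndefinedEffectError, match="no discordant pairs"):
            delta_discordant(0.005, 0.0)

    def test_equals_conditional_expectation_over_discordant_atoms(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            scenario = random_scenario(rng)
            expected = brute_theta_discordant(scenario, "A") - brute_theta_discordant(scenario, "B")
            summary = summarize_effects(scenario)
            assert summary.delta_disc == pytest.approx(expected, abs=1e-10)
            assert theta_discordant(scenario, "A") - theta_discordant(scenario, "B") == pytest.approx(
                expected, abs=1e-10
            )


class TestSummaryIdentities:
    def test_delta_disc_times_fraction_recovers_delta(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            scenario = random_scenario(rng)
            s = summarize_effects(scenario)
            assert s.delta_disc * s.discordance_fraction == pytest.approx(s.delta, abs=1e-12)
            assert s.delta == pytest.approx(s.theta_a - s.theta_b, abs=1e-12)
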