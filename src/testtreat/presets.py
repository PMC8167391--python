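"""Packaged example scenarios.

Three presets sketch published test-treatment studies; only the dysphagia
study contributes printed arm-level numbers, which the preset reproduces
exactly. Everything not printed in the study reports — accuracy values,
dependence, subgroup outcome tables — is invented here for illustration
and documented as such: these are synthetic planning sketches, not
reconstructions of the trials.
"""

from __future__ import annotations

import numpy as np

from .scenario import (
    DiseasePopulation,
    JointOutcomeModel,
    LinkRule,
    PairedTestModel,
    ScenarioModel,
    TestAccuracy,
)

__all__ = [
    "PRESETS",
    "get_preset",
    "dysphagia_worked_example",
    "DYSPHAGIA_TABLE",
]

# Printed 2x2 outcome table of the dysphagia trial: pneumonia events /
# arm size for the MBS (test A) and FEESST (test B) strategies.
DYSPHAGIA_TABLE = {"A": (14, 76), "B": (6, 50)}

# Printed arm event rates (14/76 -> 18.4%, 6/50 -> 12%) as the planning
# proportions; the printed total of 986 reproduces from these rounded
# rates under the pinned two-proportion formula.
DYSPHAGIA_RATE_A = 0.184
DYSPHAGIA_RATE_B = 0.12


def dysphagia_worked_example() -> ScenarioModel:
    """Dysphagia/aspiration-pneumonia scenario (classical design).

    Outpatients with dysphagia are randomized to a modified barium
    swallow study (MBS, test A) or flexible endoscopic evaluation of
    swallowing with sensory testing (FEESST, test B); positives receive a
    PEG tube (management I), negatives behavioral/dietary management
    (management II). Outcome is pneumonia within follow-up (binary,
    1 = pneumonia, lower is better).

    Prevalence and test accuracies are invented (no accuracy data are
    printed); the two management-II outcome rates are solved from a
    linear system so the classical arm-level event rates equal the
    printed 18.4% (MBS) and 12% (FEESST) exactly.
    """
    prevalence = 0.4
    acc_a = TestAccuracy(sensitivity=0.70, specificity=0.80)  # invented
    acc_b = TestAccuracy(sensitivity=0.90, specificity=0.85)  # invented
    e_i_pos, e_i_neg = 0.08, 0.10  # invented: pneumonia risk under PEG (I)
    # Solve e(II,+), e(II,-) so that theta_A, theta_B hit the printed rates:
    # theta_tau = a_tau e(I,+) + b_tau e(II,+) + c_tau e(I,-) + d_tau e(II,-)
    coefs = {}
    for tau, acc in (("A", acc_a), ("B", acc_b)):
        coefs[tau] = (
            prevalence * acc.sensitivity,  # diseased, positive -> I
            prevalence * (1 - acc.sensitivity),  # diseased, negative -> II
            (1 - prevalence) * (1 - acc.specificity),  # non-diseased, positive -> I
            (1 - prevalence) * acc.specificity,  # non-diseased, negative -> II
        )
    a_a, b_a, c_a, d_a = coefs["A"]
    a_b, b_b, c_b, d_b = coefs["B"]
    rhs = np.array(
        [
            DYSPHAGIA_RATE_A - a_a * e_i_pos - c_a * e_i_neg,
            DYSPHAGIA_RATE_B - a_b * e_i_pos - c_b * e_i_neg,
        ]
    )
    e_ii_pos, e_ii_neg = np.linalg.solve(np.array([[b_a, d_a], [b_b, d_b]]), rhs)
    outcomes = JointOutcomeModel.from_management_disease(
        {
            ("I", 1): e_i_pos,
            ("I", 0): e_i_neg,
            ("II", 1): float(e_ii_pos),
            ("II", 0): float(e_ii_neg),
        }
    )
    return ScenarioModel(
        population=DiseasePopulation(prevalence),
        tests=PairedTestModel(acc_a, acc_b),
        outcomes=outcomes,
        link=LinkRule(),
    ).require_valid()


def paired_worked_example() -> ScenarioModel:
    """Generic paired-planning scenario: prevalence 0.30, test A with
    sensitivity 0.90 / specificity 0.80, test B with 0.70 / 0.90,
    conditionally independent. Discordance fraction 0.284. The outcome
    table (1 = favourable, higher is better) gives management I a benefit
    in the diseased and management II a benefit in the non-diseased."""
    outcomes = JointOutcomeModel.from_management_disease(
        {("I", 1): 0.70, ("II", 1): 0.50, ("I", 0): 0.85, ("II", 0): 0.95}
    )
    return ScenarioModel(
        population=DiseasePopulation(0.30),
        tests=PairedTestModel(TestAccuracy(0.90, 0.80), TestAccuracy(0.70, 0.90)),
        outcomes=outcomes,
    ).require_valid()


def foam_sketch() -> ScenarioModel:
    """FOAM-style discordant-pairs sketch (synthetic).

    Tubal-patency testing in subfertile women: HyFoSy (test A) vs HSG
    (test B), with discordant results randomized. Outcome is ongoing
    pregnancy within 12 months (binary, higher is better). All parameter
    values — prevalence of tubal pathology, accuracies, a positive
    conditional dependence, and the outcome table — are invented; the
    study itself reports no such planning numbers.
    """
    tests = PairedTestModel.from_correlation(
        TestAccuracy(0.85, 0.90),
        TestAccuracy(0.80, 0.88),
        corr_diseased=0.3,
        corr_nondiseased=0.3,
    )
    outcomes = JointOutcomeModel.from_management_disease(
        {("I", 1): 0.35, ("II", 1): 0.22, ("I", 0): 0.40, ("II", 0): 0.48}
    )
    return ScenarioModel(
        population=DiseasePopulation(0.25), tests=tests, outcomes=outcomes
    ).require_valid()


def doppler_us_sketch() -> ScenarioModel:
    """Doppler-ultrasonography single-test-disclosure sketch (synthetic).

    Suspected intrauterine growth retardation: Doppler US of the
    umbilical artery as test A, randomized disclosure vs non-disclosure
    (non-disclosed patients receive the standard management I,
    hospitalization). Outcome is a favourable perinatal course (binary,
    higher is better). All parameter values are invented.
    """
    outcomes = JointOutcomeModel.from_management_disease(
        {("I", 1): 0.75, ("II", 1): 0.60, ("I", 0): 0.82, ("II", 0): 0.92}
    )
    return ScenarioModel(
        population=DiseasePopulation(0.30),
        tests=PairedTestModel(TestAccuracy(0.80, 0.85), TestAccuracy(0.80, 0.85)),
        outcomes=outcomes,
    ).require_valid()


PRESETS = {
    "dysphagia_worked_example": dysphagia_worked_example,
    "paired_worked_example": paired_worked_example,
    "foam_sketch": foam_sketch,
    "doppler_us_sketch": doppler_us_sketch,
}


def get_preset(name: str) -> ScenarioModel:
    """Look up a packaged preset scenario by name."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


# ---------------------------------------------------------------------------
# benchmark suites for simulation-based verification
# ---------------------------------------------------------------------------

def _from_management_disease(prev, acc_a, acc_b, e_md, scale="binary", sd=None, corr=(0.0, 0.0)):
    tests = PairedTestModel.from_correlation(
        TestAccuracy(*acc_a), TestAccuracy(*acc_b), corr[0], corr[1]
    )
    outcomes = JointOutcomeModel.from_management_disease(e_md, outcome_scale=scale, sd=sd)
    return ScenarioModel(
        population=DiseasePopulation(prev), tests=tests, outcomes=outcomes
    ).require_valid()


def _discordant_only_effect(prev, acc_a, acc_b, disc_vals, scale="binary", sd=None):
    """Scenario whose managements differ only in the discordant strata:
    (e_I, e_II) for the (+,-) cell, (e_I, e_II) for the (-,+) cell, and a
    management-independent value in the concordant cells."""
    tests = PairedTestModel(TestAccuracy(*acc_a), TestAccuracy(*acc_b))
    (pm_i, pm_ii), (mp_i, mp_ii), conc = disc_vals
    table = {}
    for ta in (1, 0):
        for tb in (1, 0):
            for d in (1, 0):
                if ta == tb:
                    table[("I", ta, tb, d)] = conc
                    table[("II", ta, tb, d)] = conc
                elif ta == 1:
                    table[("I", ta, tb, d)] = pm_i
                    table[("II", ta, tb, d)] = pm_ii
                else:
                    table[("I", ta, tb, d)] = mp_i
                    table[("II", ta, tb, d)] = mp_ii
    outcomes = JointOutcomeModel(scale, table, sd=sd)
    return ScenarioModel(
        population=DiseasePopulation(prev), tests=tests, outcomes=outcomes
    ).require_valid()


def power_benchmark_suite():
    """Planning scenarios used to verify the closed-form sample sizes by
    simulation, spanning binary/continuous outcomes and the classical and
    discordant designs. Effects are sized so the trials stay in the
    hundreds-to-low-thousands range where the normal approximation is the
    intended operating regime. Returns (name, scenario, design) triples.
    """
    return [
        (
            "binary_classical",
            _from_management_disease(
                0.40, (0.90, 0.90), (0.60, 0.60),
                {("I", 1): 0.20, ("II", 1): 0.70, ("I", 0): 0.60, ("II", 0): 0.30},
            ),
            "classical",
        ),
        (
            "binary_discordant",
            _discordant_only_effect(
                0.30, (0.90, 0.80), (0.70, 0.90), ((0.50, 0.35), (0.45, 0.55), 0.40)
            ),
            "discordant",
        ),
        (
            "continuous_classical",
            _from_management_disease(
                0.40, (0.95, 0.90), (0.60, 0.65),
                {("I", 1): 0.80, ("II", 1): 0.30, ("I", 0): 0.10, ("II", 0): 0.50},
                scale="continuous", sd=0.6,
            ),
            "classical",
        ),
        (
            "continuous_discordant",
            _discordant_only_effect(
                0.30, (0.90, 0.80), (0.70, 0.90), ((0.30, 0.05), (0.10, 0.25), 0.0),
                scale="continuous", sd=0.7,
            ),
            "discordant",
        ),
        (
            "binary_classical_dependent",
            _from_management_disease(
                0.35, (0.90, 0.85), (0.65, 0.60),
                {("I", 1): 0.25, ("II", 1): 0.65, ("I", 0): 0.55, ("II", 0): 0.30},
                corr=(0.3, 0.3),
            ),
            "classical",
        ),
    ]


def null_scenario():
    """Exact null: identical tests (so both strategies induce the same
    management distribution) with a non-trivial management-by-disease
    outcome table. theta_A == theta_B and Delta^disc == 0 by symmetry."""
    return _from_management_disease(
        0.30, (0.80, 0.85), (0.80, 0.85),
        {("I", 1): 0.30, ("II", 1): 0.50, ("I", 0): 0.25, ("II", 0): 0.15},
    )


def adaptive_null_planning_scenario():
    """Planning scenario for type-I-error checks of the adaptive rule: a
    clearly non-null planning assumption whose prevalence (0.50) is
    misspecified relative to the null truth (0.30), so the blinded
    interim look genuinely changes the target sample size."""
    return _from_management_disease(
        0.50, (0.90, 0.90), (0.60, 0.60),
        {("I", 1): 0.20, ("II", 1): 0.70, ("I", 0): 0.60, ("II", 0): 0.30},
    )
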