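"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own computation paths:
the joint result table is solved by hand from marginals + covariance, and
expectations are obtained by enumerating the eight (t_A, t_B, d) atoms.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from testtreat import (
    DiseasePopulation,
    JointOutcomeModel,
    PairedTestModel,
    ScenarioModel,
    TestAccuracy,
    frechet_bounds,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_joint_cells(p_a: float, p_b: float, cov: float) -> dict:
    """Solve the 2x2 joint table of two Bernoulli indicators from the two
    marginals and their covariance (linear system solved by hand)."""
    p11 = p_a * p_b + cov
    return {
        (1, 1): p11,
        (1, 0): p_a - p11,
        (0, 1): p_b - p11,
        (0, 0): 1.0 - p_a - p_b + p11,
    }


def brute_atoms(scenario: ScenarioModel):
    """Enumerate the eight (t_a, t_b, d) atoms with their probabilities."""
    prev = scenario.population.prevalence
    for d in (1, 0):
        p_a = scenario.tests.accuracy_a.positive_prob(d)
        p_b = scenario.tests.accuracy_b.positive_prob(d)
        cells = brute_joint_cells(p_a, p_b, scenario.tests.cov(d))
        pd = prev if d else 1.0 - prev
        for (ta, tb), p in cells.items():
            yield ta, tb, d, p * pd


def brute_theta(scenario: ScenarioModel, tau: str) -> float:
    """E(Y | followed test = tau) by atom enumeration."""
    total = 0.0
    for ta, tb, d, p in brute_atoms(scenario):
        t = ta if tau == "A" else tb
        m = scenario.link.management(t)
        total += scenario.outcomes.expected_outcome(m, ta, tb, d) * p
    return total


def brute_theta_discordant(scenario: ScenarioModel, tau: str) -> float:
    num = den = 0.0
    for ta, tb, d, p in brute_atoms(scenario):
        if ta == tb:
            continue
        t = ta if tau == "A" else tb
        m = scenario.link.management(t)
        num += scenario.outcomes.expected_outcome(m, ta, tb, d) * p
        den += p
    return num / den


def random_scenario(
    rng: np.random.Generator,
    scale: str = "binary",
    concordant_null: bool = False,
) -> ScenarioModel:
    """Random valid scenario. With ``concordant_null`` the two managements
    share the outcome in every concordant stratum, confining any effect
    to the discordant cells."""
    prev = rng.uniform(0.05, 0.95)
    acc = [TestAccuracy(rng.uniform(0.55, 0.99), rng.uniform(0.55, 0.99)) for _ in range(2)]
    covs = []
    for d in (1, 0):
        lo, hi = frechet_bounds(acc[0].positive_prob(d), acc[1].positive_prob(d))
        covs.append(rng.uniform(lo, hi))
    tests = PairedTestModel(acc[0], acc[1], cov_diseased=covs[0], cov_nondiseased=covs[1])
    table = {}
    for ta in (1, 0):
        for tb in (1, 0):
            for d in (1, 0):
                if concordant_null and ta == tb:
                    shared = rng.uniform(0.05, 0.95)
                    table[("I", ta, tb, d)] = shared
                    table[("II", ta, tb, d)] = shared
                else:
                    table[("I", ta, tb, d)] = rng.uniform(0.05, 0.95)
                    table[("II", ta, tb, d)] = rng.uniform(0.05, 0.95)
    sd = None if scale == "binary" else rng.uniform(0.5, 2.0)
    outcomes = JointOutcomeModel(scale, table, sd=sd)
    return ScenarioModel(population=DiseasePopulation(prev), tests=tests, outcomes=outcomes)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def worked_population() -> DiseasePopulation:
    return DiseasePopulation(0.3)


@pytest.fixture
def worked_tests() -> PairedTestModel:
    """Prevalence-0.3 planning setup: test A 0.90/0.80, test B 0.70/0.90,
    conditionally independent. Discordance fraction 0.284."""
    return PairedTestModel(TestAccuracy(0.9, 0.8), TestAccuracy(0.7, 0.9))


@pytest.fixture
def worked_scenario(worked_population, worked_tests) -> ScenarioModel:
    outcomes = JointOutcomeModel.from_management_disease(
        {("I", 1): 0.70, ("II", 1): 0.50, ("I", 0): 0.85, ("II", 0): 0.95}
    )
    return ScenarioModel(population=worked_population, tests=worked_tests, outcomes=outcomes)
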