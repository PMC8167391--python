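"""Effect-size derivations for randomized test-treatment trials.

Two equivalent routes to the planning effect Delta = theta_A - theta_B are
implemented:

* the *unpaired* expansion, summing the per-test planning outcomes
  mu^tau_{mtd} over the result/disease strata of the test actually
  followed (:func:`theta_unpaired`);
* the *paired* expansion over the joint result distribution, where all
  concordant strata cancel (both tests imply the same management) and
  the effect reduces to a probability-weighted sum over the four
  reclassification moves FP->TN, TN->FP, FN->TP, TP->FN
  (:func:`delta_paired`, :func:`delta_paired_from_joint`).

Moves describe replacing strategy B by strategy A in a single patient
("what changes when the new test's result is followed instead of the
comparator's"); the sign of Delta flips under the reverse convention.

The discordant-pairs design targets the conditional effect
Delta^disc = Delta / P(R_A != R_B) in the discordant subpopulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenario import (
    DiseasePopulation,
    MoveEffects,
    PairedTestModel,
    ScenarioModel,
    joint_result_probs,
    mu_from_joint,
)

__all__ = [
    "MoveProbabilities",
    "EffectSummary",
    "UndefinedEffectError",
    "theta_unpaired",
    "theta_discordant",
    "move_probabilities",
    "discordance_fraction",
    "delta_paired",
    "delta_paired_from_joint",
    "delta_discordant",
    "summarize_effects",
]


class UndefinedEffectError(ZeroDivisionError):
    """Raised when a conditional effect is undefined (no discordant pairs)."""


@dataclass(frozen=True)
class MoveProbabilities:
    """Unconditional probabilities of the four reclassification moves.

    Each is the probability that a randomly drawn patient belongs to the
    corresponding discordant stratum, *including* the disease-status
    weight P(D=d). Their sum is exactly the discordance fraction
    P(R_A != R_B).
    """

    p_fp_to_tn: float
    p_tn_to_fp: float
    p_fn_to_tp: float
    p_tp_to_fn: float

    @property
    def total(self) -> float:
        return self.p_fp_to_tn + self.p_tn_to_fp + self.p_fn_to_tp + self.p_tp_to_fn


@dataclass(frozen=True)
class EffectSummary:
    """Planning effect sizes of a scenario on both scales.

    ``delta_disc`` is ``nan`` when the discordance fraction is zero (the
    conditional effect is undefined; the identity
    delta_disc * discordance_fraction == delta holds whenever it is
    defined).
    """

    theta_a: float
    theta_b: float
    delta: float
    discordance_fraction: float
    delta_disc: float


def theta_unpaired(scenario: ScenarioModel, tau: str) -> float:
    """Expected outcome theta_tau = E(Y | followed test = tau).

    Expands over the followed test's result and the disease status:

        theta_tau = sum_{t,d} mu^tau_{m(t),t,d} P(R_tau=t | D=d) P(D=d)

    with mu^tau the planning table derived from the joint outcome model.
    """
    scenario.require_valid()
    mu = mu_from_joint(scenario, tau)
    acc = scenario.tests.accuracy(tau)
    total = 0.0
    for d in (1, 0):
        pd = scenario.population.prob(d)
        if pd == 0.0:
            continue
        for t in (1, 0):
            pt = acc.positive_prob(d) if t else 1.0 - acc.positive_prob(d)
            if pt == 0.0:
                continue
            m = scenario.link.management(t)
            total += mu.value(tau, m, t, d) * pt * pd
    return total


def theta_discordant(scenario: ScenarioModel, tau: str) -> float:
    """Expected outcome among discordant patients when test ``tau`` is
    followed: theta^disc_tau = E(Y | followed = tau, R_A != R_B).

    Raises
    ------
    UndefinedEffectError
        If the discordance fraction is zero.
    """
    scenario.require_valid()
    e = scenario.outcomes.e_array
    num = 0.0
    den = 0.0
    for d in (1, 0):
        pd = scenario.population.prob(d)
        joint = joint_result_probs(scenario.tests, d)
        for ta, tb in ((1, 0), (0, 1)):
            w = joint[ta, tb] * pd
            if w == 0.0:
                continue
            t = ta if tau == "A" else tb
            mi = int(scenario.link.management_index(t))
            num += e[mi, ta, tb, d] * w
            den += w
    if den == 0.0:
        raise UndefinedEffectError("no discordant pairs: P(R_A != R_B) = 0")
    return num / den


def outcome_variance_unpaired(scenario: ScenarioModel, tau: str) -> float:
    """Marginal outcome variance Var(Y | followed test = tau).

    For a continuous outcome this combines the residual variance with the
    spread of the conditional means across the (t_A, t_B, d) strata of
    the arm — the quantity a planning guess about "the variation of Y"
    refers to, larger than the residual sd whenever strata differ.
    """
    scenario.require_valid()
    e = scenario.outcomes.e_array
    theta = 0.0
    second = 0.0
    for d in (1, 0):
        pd = scenario.population.prob(d)
        joint = joint_result_probs(scenario.tests, d)
        for ta in (1, 0):
            for tb in (1, 0):
                w = joint[ta, tb] * pd
                if w == 0.0:
                    continue
                t = ta if tau == "A" else tb
                mi = int(scenario.link.management_index(t))
                theta += e[mi, ta, tb, d] * w
                second += e[mi, ta, tb, d] ** 2 * w
    between = second - theta**2
    if scenario.outcomes.outcome_scale == "binary":
        return theta * (1.0 - theta)
    return scenario.outcomes.sd**2 + between


def outcome_variance_discordant(scenario: ScenarioModel, tau: str) -> float:
    """Var(Y | followed test = tau, R_A != R_B), the planning variance of
    the discordant-pairs analysis arm."""
    scenario.require_valid()
    e = scenario.outcomes.e_array
    num1 = num2 = den = 0.0
    for d in (1, 0):
        pd = scenario.population.prob(d)
        joint = joint_result_probs(scenario.tests, d)
        for ta, tb in ((1, 0), (0, 1)):
            w = joint[ta, tb] * pd
            if w == 0.0:
                continue
            t = ta if tau == "A" else tb
            mi = int(scenario.link.management_index(t))
            num1 += e[mi, ta, tb, d] * w
            num2 += e[mi, ta, tb, d] ** 2 * w
            den += w
    if den == 0.0:
        raise UndefinedEffectError("no discordant pairs: P(R_A != R_B) = 0")
    mean = num1 / den
    between = num2 / den - mean**2
    if scenario.outcomes.outcome_scale == "binary":
        return mean * (1.0 - mean)
    return scenario.outcomes.sd**2 + between


def move_probabilities(tests: PairedTestModel, population: DiseasePopulation) -> MoveProbabilities:
    """Probabilities of the four moves induced by replacing strategy B
    with strategy A.

    A patient "moves" only when the tests disagree. In the diseased
    stratum, (R_A=+, R_B=-) means the comparator misses the disease while
    the new test finds it — an FN->TP move; (R_A=-, R_B=+) is the reverse
    TP->FN move. In the non-diseased stratum, (R_A=-, R_B=+) corrects a
    false positive (FP->TN) and (R_A=+, R_B=-) creates one (TN->FP).
    """
    joint_pos = joint_result_probs(tests, 1)
    joint_neg = joint_result_probs(tests, 0)
    prev = population.prevalence
    return MoveProbabilities(
        p_fn_to_tp=joint_pos[1, 0] * prev,
        p_tp_to_fn=joint_pos[0, 1] * prev,
        p_tn_to_fp=joint_neg[1, 0] * (1.0 - prev),
        p_fp_to_tn=joint_neg[0, 1] * (1.0 - prev),
    )


def discordance_fraction(tests: PairedTestModel, population: DiseasePopulation) -> float:
    """P(R_A != R_B) in the target population.

    Equals the sum of the four move probabilities; decreasing either
    conditional covariance (more negative dependence) increases it, so it
    is maximized at the lower Fréchet bound and minimized at the upper.
    """
    return move_probabilities(tests, population).total


def delta_paired(
    tests: PairedTestModel, population: DiseasePopulation, moves: MoveEffects
) -> float:
    """Planning effect Delta from elicited move effects.

        Delta = D(FP->TN) P(FP->TN) + D(TN->FP) P(TN->FP)
              + D(FN->TP) P(FN->TP) + D(TP->FN) P(TP->FN)

    Only the four discordant strata contribute; concordant results imply
    the same management in both strategies.
    """
    p = move_probabilities(tests, population)
    return (
        moves.delta_fp_to_tn * p.p_fp_to_tn
        + moves.tn_to_fp * p.p_tn_to_fp
        + moves.delta_fn_to_tp * p.p_fn_to_tp
        + moves.tp_to_fn * p.p_tp_to_fn
    )


def delta_paired_from_joint(scenario: ScenarioModel) -> float:
    """Planning effect Delta from the full joint outcome model.

        Delta = sum_{t_A != t_B, d} [e(m(t_A), t_A, t_B, d)
                                     - e(m(t_B), t_A, t_B, d)]
                                    P(R_A=t_A, R_B=t_B | D=d) P(D=d)

    Concordant strata vanish identically because m(t_A) = m(t_B) there.
    Equals theta_unpaired(A) - theta_unpaired(B) for every valid scenario
    (both are expectations over the same eight atoms).
    """
    scenario.require_valid()
    e = scenario.outcomes.e_array
    link = scenario.link
    total = 0.0
    for d in (1, 0):
        pd = scenario.population.prob(d)
        joint = joint_result_probs(scenario.tests, d)
        for ta, tb in ((1, 0), (0, 1)):
            w = joint[ta, tb] * pd
            if w == 0.0:
                continue
            m_a = int(link.management_index(ta))
            m_b = int(link.management_index(tb))
            total += (e[m_a, ta, tb, d] - e[m_b, ta, tb, d]) * w
    return total


def delta_discordant(delta: float, disc_fraction: float) -> float:
    """Conditional effect in the discordant subpopulation,
    Delta^disc = Delta / P(R_A != R_B).

    Raises
    ------
    UndefinedEffectError
        If ``disc_fraction`` is zero (no discordant pairs exist).
    """
    if disc_fraction == 0.0:
        raise UndefinedEffectError("no discordant pairs: P(R_A != R_B) = 0")
    if not (0.0 < disc_fraction <= 1.0):
        raise ValueError(f"discordance fraction must lie in (0, 1], got {disc_fraction!r}")
    return delta / disc_fraction


def summarize_effects(scenario: ScenarioModel) -> EffectSummary:
    """All planning effect quantities of a scenario in one pass."""
    theta_a = theta_unpaired(scenario, "A")
    theta_b = theta_unpaired(scenario, "B")
    delta = delta_paired_from_joint(scenario)
    frac = discordance_fraction(scenario.tests, scenario.population)
    delta_disc = delta / frac if frac > 0.0 else float("nan")
    return EffectSummary(
        theta_a=theta_a,
        theta_b=theta_b,
        delta=delta,
        discordance_fraction=frac,
        delta_disc=delta_disc,
    )
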