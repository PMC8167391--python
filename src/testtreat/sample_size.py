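"""Closed-form sample-size calculators.

Binary outcomes use the normal-approximation sample size for the
chi-squared test of two independent proportions with the variance pooled
under H0 and unpooled under H1, no continuity correction:

    n_1 = [ z_{1-a/s} sqrt(pbar qbar (1 + 1/r)) + z_{pow} sqrt(p1 q1 + p2 q2 / r) ]^2
          / (p1 - p2)^2

with allocation ratio r = n_2 / n_1 and pooled rate
pbar = (p1 + r p2) / (1 + r). Continuous outcomes use the z-based
two-sample formula n_1 = (z_{1-a/s} + z_{pow})^2 sigma^2 (1 + 1/r) / Delta^2.
Per-arm sizes are rounded up.

The discordant-pairs design is sized on the conditional effect in the
discordant subpopulation; the screened cohort needed to yield n_disc
discordant patients is n_disc divided by the discordance fraction,
rounded up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .effect_size import (
    discordance_fraction,
    outcome_variance_discordant,
    outcome_variance_unpaired,
    theta_discordant,
    theta_unpaired,
)
from .scenario import ScenarioModel

__all__ = [
    "SampleSizeResult",
    "ZeroEffectError",
    "n_two_proportions",
    "n_two_means",
    "n_discordant_design",
    "n_classical_from_scenario",
    "n_discordant_from_scenario",
]

_EFFECT_TOL = 1e-12


class ZeroEffectError(ValueError):
    """Raised when the assumed effect is zero and no finite n exists."""


@dataclass(frozen=True)
class SampleSizeResult:
    """Result of a sample-size calculation.

    ``n_per_arm`` is the size of the reference arm (arm 1); the other arm
    holds ``ceil(allocation_ratio * n_per_arm)`` patients. For the
    discordant design ``n_disc`` is the number of randomized (discordant)
    patients and ``n_screened`` the total cohort that must undergo both
    tests to yield them.
    """

    n_per_arm: int
    n_total: int
    alpha: float
    power: float
    sides: int
    allocation_ratio: float
    n_disc: int | None = None
    n_screened: int | None = None


def _check_common(alpha: float, power: float, sides: int, allocation_ratio: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    if not (0.0 < power < 1.0):
        raise ValueError(f"power must lie in (0, 1), got {power!r}")
    if power <= alpha:
        raise ValueError(f"power ({power}) must exceed alpha ({alpha})")
    if sides not in (1, 2):
        raise ValueError(f"sides must be 1 or 2, got {sides!r}")
    if not allocation_ratio > 0:
        raise ValueError(f"allocation ratio must be positive, got {allocation_ratio!r}")


def _package(n1: float, alpha, power, sides, r) -> SampleSizeResult:
    n_per_arm = int(math.ceil(n1 - 1e-9))  # guard float noise at integer boundaries
    n_other = int(math.ceil(r * n_per_arm - 1e-9))
    return SampleSizeResult(
        n_per_arm=n_per_arm,
        n_total=n_per_arm + n_other,
        alpha=alpha,
        power=power,
        sides=sides,
        allocation_ratio=r,
    )


def n_two_proportions(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    sides: int = 2,
    allocation_ratio: float = 1.0,
) -> SampleSizeResult:
    """Sample size for the chi-squared test of two independent proportions.

    Parameters
    ----------
    p1, p2
        Assumed event proportions in the two arms, both in (0, 1).
    alpha, power, sides, allocation_ratio
        Significance level, target power, sidedness of the test, and
        allocation ratio r = n2/n1.

    Raises
    ------
    ZeroEffectError
        If ``p1 == p2``.
    """
    _check_common(alpha, power, sides, allocation_ratio)
    for name, p in (("p1", p1), ("p2", p2)):
        if not (0.0 < p < 1.0):
            raise ValueError(f"{name} must lie in (0, 1), got {p!r}")
    if abs(p1 - p2) < _EFFECT_TOL:
        raise ZeroEffectError("p1 == p2: no effect to detect, sample size is unbounded")
    r = allocation_ratio
    z_a = stats.norm.ppf(1.0 - alpha / sides)
    z_b = stats.norm.ppf(power)
    pbar = (p1 + r * p2) / (1.0 + r)
    qbar = 1.0 - pbar
    num = (
        z_a * math.sqrt(pbar * qbar * (1.0 + 1.0 / r))
        + z_b * math.sqrt(p1 * (1.0 - p1) + p2 * (1.0 - p2) / r)
    ) ** 2
    n1 = num / (p1 - p2) ** 2
    return _package(n1, alpha, power, sides, r)


def n_two_means(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    sides: int = 2,
    allocation_ratio: float = 1.0,
) -> SampleSizeResult:
    """Sample size for a two-sample comparison of means (z approximation).

    ``delta`` is the assumed mean difference and ``sd`` the common
    residual standard deviation of the outcome.
    """
    _check_common(alpha, power, sides, allocation_ratio)
    if not sd > 0:
        raise ValueError(f"sd must be positive, got {sd!r}")
    if abs(delta) < _EFFECT_TOL:
        raise ZeroEffectError("delta == 0: no effect to detect, sample size is unbounded")
    r = allocation_ratio
    z_a = stats.norm.ppf(1.0 - alpha / sides)
    z_b = stats.norm.ppf(power)
    n1 = (z_a + z_b) ** 2 * sd**2 * (1.0 + 1.0 / r) / delta**2
    return _package(n1, alpha, power, sides, r)


def n_discordant_design(
    disc_fraction: float,
    scenario: ScenarioModel | None = None,
    p_disc_a: float | None = None,
    p_disc_b: float | None = None,
    delta_disc: float | None = None,
    sd: float | None = None,
    alpha: float = 0.05,
    power: float = 0.80,
    sides: int = 2,
) -> SampleSizeResult:
    """Sample size for the discordant-pairs design.

    The randomized comparison happens inside the discordant subpopulation,
    so the matching two-sample formula is applied to the conditional
    arm-level quantities there; the screened cohort is inflated as
    ``n_screened = ceil(n_disc / disc_fraction)``.

    Inputs may be given either as a full ``scenario`` (arm rates / effect
    are derived from it), as discordant arm proportions ``p_disc_a`` /
    ``p_disc_b`` (binary outcome), or as ``delta_disc`` + ``sd``
    (continuous outcome).

    Raises
    ------
    ZeroEffectError
        If the conditional effect is zero.
    ValueError
        If ``disc_fraction`` is not in (0, 1] ("no discordance").
    """
    if not (0.0 < disc_fraction <= 1.0):
        raise ValueError(
            f"discordance fraction must lie in (0, 1], got {disc_fraction!r}: "
            "a design restricted to discordant pairs is infeasible without discordance"
        )
    if scenario is not None:
        scenario.require_valid()
        if scenario.outcomes.outcome_scale == "binary":
            p_disc_a = theta_discordant(scenario, "A")
            p_disc_b = theta_discordant(scenario, "B")
            delta_disc = None
        else:
            delta_disc = theta_discordant(scenario, "A") - theta_discordant(scenario, "B")
            # marginal outcome sd in the discordant arms (residual +
            # between-stratum spread), not just the residual sd
            sd = math.sqrt(
                0.5
                * (
                    outcome_variance_discordant(scenario, "A")
                    + outcome_variance_discordant(scenario, "B")
                )
            )
            p_disc_a = p_disc_b = None
    if p_disc_a is not None and p_disc_b is not None:
        base = n_two_proportions(p_disc_a, p_disc_b, alpha=alpha, power=power, sides=sides)
    elif delta_disc is not None and sd is not None:
        base = n_two_means(delta_disc, sd, alpha=alpha, power=power, sides=sides)
    else:
        raise ValueError(
            "provide a scenario, binary discordant arm proportions, or delta_disc with sd"
        )
    n_disc = base.n_total
    n_screened = int(math.ceil(n_disc / disc_fraction - 1e-9))
    return SampleSizeResult(
        n_per_arm=base.n_per_arm,
        n_total=base.n_total,
        alpha=alpha,
        power=power,
        sides=sides,
        allocation_ratio=1.0,
        n_disc=n_disc,
        n_screened=n_screened,
    )


def n_classical_from_scenario(
    scenario: ScenarioModel,
    alpha: float = 0.05,
    power: float = 0.80,
    sides: int = 2,
) -> SampleSizeResult:
    """Classical-design sample size from a full scenario.

    Computes the arm-level expected outcomes theta_A, theta_B and
    dispatches to the matching two-sample formula: proportions for a
    binary outcome, means (with the scenario's residual sd) for a
    continuous outcome.
    """
    scenario.require_valid()
    theta_a = theta_unpaired(scenario, "A")
    theta_b = theta_unpaired(scenario, "B")
    if abs(theta_a - theta_b) < _EFFECT_TOL:
        raise ZeroEffectError("theta_A == theta_B: null scenario has no finite sample size")
    if scenario.outcomes.outcome_scale == "binary":
        return n_two_proportions(theta_a, theta_b, alpha=alpha, power=power, sides=sides)
    # marginal outcome sd per arm (residual + between-stratum spread)
    sd = math.sqrt(
        0.5 * (outcome_variance_unpaired(scenario, "A") + outcome_variance_unpaired(scenario, "B"))
    )
    return n_two_means(theta_a - theta_b, sd, alpha=alpha, power=power, sides=sides)


def n_discordant_from_scenario(
    scenario: ScenarioModel,
    alpha: float = 0.05,
    power: float = 0.80,
    sides: int = 2,
) -> SampleSizeResult:
    """Discordant-design sample size from a full scenario (convenience
    wrapper deriving the discordance fraction and conditional effect)."""
    frac = discordance_fraction(scenario.tests, scenario.population)
    return n_discordant_design(frac, scenario=scenario, alpha=alpha, power=power, sides=sides)
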