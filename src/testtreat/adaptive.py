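"""Blinded, prevalence-based adaptive sample-size re-estimation.

The planning effect of a test-treatment trial combines disease
prevalence, test accuracy and subgroup outcome assumptions; of these,
prevalence can be re-estimated mid-trial *without unblinding* whenever a
reference standard is applied in a blinded manner alongside the tests.
The procedure implemented here:

1. Plan the trial under a planning scenario; compute the initial n.
2. After a fixed fraction of recruitment (default 50%), estimate the
   prevalence as the observed fraction of reference-standard positives
   among interim patients — no outcome values, no arm labels are used.
3. Re-plan with the prevalence replaced by its interim estimate and all
   other planning assumptions held fixed. If the re-estimated n exceeds
   a pre-specified feasibility cap the trial stops for futility;
   otherwise recruitment continues to max(initial n, re-estimated n)
   (the target is never shrunk below the initial plan by default).
4. The final analysis is performed at the achieved sample size with the
   unadjusted significance level: re-estimating a nuisance parameter
   blinded to outcomes and arms does not inflate the type I error.

All recruited patients, including the interim ones, count toward the
re-estimated target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .sample_size import SampleSizeResult, ZeroEffectError, n_classical_from_scenario
from .scenario import ScenarioModel
from .simulator import (
    DegenerateAnalysisError,
    TrialResult,
    _analyze,
    _cohort_arrays,
    _draw_outcomes,
    _rng,
    run_classical,
    simulate_cohort,
)

__all__ = [
    "AdaptivePlan",
    "InterimDecision",
    "AdaptiveTrialOutcome",
    "OperatingCharacteristics",
    "interim_reestimate",
    "run_adaptive_trial",
    "operating_characteristics",
]

ACTIONS = ("continue_as_planned", "increase_to_n", "stop_futility")


@dataclass(frozen=True)
class AdaptivePlan:
    """Pre-specified adaptive design for a classical test-treatment RCT.

    Parameters
    ----------
    planning_scenario
        Scenario encoding the planning assumptions (prevalence, accuracy,
        dependence, subgroup outcomes).
    n_max
        Feasibility cap: if the re-estimated total n exceeds it, the
        trial stops for futility. Must be at least the initial n.
    interim_fraction
        Fraction of the initially planned sample recruited before the
        blinded interim look (timing rounded up to a whole patient).
    allow_decrease
        If True the target may shrink to the re-estimated n when that is
        below the initial plan; default keeps the initial n (conservative).
    """

    planning_scenario: ScenarioModel
    n_max: int
    interim_fraction: float = 0.5
    alpha: float = 0.05
    power: float = 0.80
    sides: int = 2
    allow_decrease: bool = False

    def initial_sample_size(self) -> SampleSizeResult:
        return n_classical_from_scenario(
            self.planning_scenario, alpha=self.alpha, power=self.power, sides=self.sides
        )

    def validate(self) -> None:
        if not (0.0 < self.interim_fraction < 1.0):
            raise ValueError(f"interim_fraction must lie in (0, 1), got {self.interim_fraction!r}")
        n_init = self.initial_sample_size().n_total
        if self.n_max < n_init:
            raise ValueError(f"n_max ({self.n_max}) must be at least the initial n ({n_init})")

    def interim_n(self) -> int:
        return int(math.ceil(self.interim_fraction * self.initial_sample_size().n_total))


@dataclass(frozen=True)
class InterimDecision:
    """Outcome of the blinded interim look."""

    prevalence_hat: float
    n_reestimated: int
    action: str
    n_initial: int
    n_final_target: int


@dataclass
class AdaptiveTrialOutcome:
    """One adaptive trial: the interim decision plus, unless stopped for
    futility, the final analyzed trial."""

    decision: InterimDecision
    trial: Optional[TrialResult]
    stopped_for_futility: bool
    final_n: int

    @property
    def p_value(self) -> Optional[float]:
        return None if self.trial is None else self.trial.p_value


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo operating characteristics of the adaptive procedure.

    ``rejection_rate`` counts futility-stopped replicates as
    non-rejections (denominator = all replicates);
    ``completed_rejection_rate`` conditions on completion.
    """

    rejection_rate: float
    mc_standard_error: float
    completed_rejection_rate: float
    futility_rate: float
    mean_final_n: float
    final_n_quantiles: Dict[str, float]
    n_reps: int
    seed: int
    alpha: float


def _reestimate_n(plan: AdaptivePlan, prevalence_hat: float) -> int:
    """Re-planned total n at the interim prevalence estimate; inf-like
    sentinel (n_max + 1) when the re-planned effect vanishes."""
    updated = plan.planning_scenario.with_prevalence(prevalence_hat)
    try:
        res = n_classical_from_scenario(
            updated, alpha=plan.alpha, power=plan.power, sides=plan.sides
        )
    except ZeroEffectError:
        warnings.warn(
            "degenerate re-estimation: the re-planned effect is zero at "
            f"prevalence_hat={prevalence_hat:.4g}; stopping for futility",
            RuntimeWarning,
            stacklevel=3,
        )
        return plan.n_max + 1
    return res.n_total


def interim_reestimate(plan: AdaptivePlan, interim_records) -> InterimDecision:
    """Blinded interim re-estimation from the reference-standard results.

    ``interim_records`` is a DataFrame (or mapping) with a ``d`` column —
    the blinded reference-standard disease status of every interim
    patient. Only this column is read: outcome values and arm labels
    never enter the decision.
    """
    plan.validate()
    if isinstance(interim_records, pd.DataFrame):
        d = interim_records["d"].to_numpy()
    else:
        d = np.asarray(interim_records["d"])
    if len(d) == 0:
        raise ValueError("interim re-estimation requires at least one patient")
    prevalence_hat = float(np.mean(d))
    if prevalence_hat in (0.0, 1.0):
        warnings.warn(
            f"degenerate interim prevalence estimate {prevalence_hat:g}; "
            "the re-planned scenario sits on the boundary",
            RuntimeWarning,
            stacklevel=2,
        )
    n_init = plan.initial_sample_size().n_total
    n_re = _reestimate_n(plan, prevalence_hat)
    if n_re > plan.n_max:
        action = "stop_futility"
        n_target = n_init
    elif n_re <= n_init:
        action = "continue_as_planned"
        n_target = n_re if plan.allow_decrease else n_init
        n_target = max(n_target, len(d))  # never below what is already recruited
    else:
        action = "increase_to_n"
        n_target = n_re
    return InterimDecision(
        prevalence_hat=prevalence_hat,
        n_reestimated=n_re,
        action=action,
        n_initial=n_init,
        n_final_target=n_target,
    )


def run_adaptive_trial(true_scenario: ScenarioModel, plan: AdaptivePlan, seed) -> AdaptiveTrialOutcome:
    """Simulate one adaptive trial under ``true_scenario``.

    The true scenario may (and typically does) differ from the planning
    scenario — that mismatch is what re-estimation corrects for. Recruits
    to the interim point, applies the blinded rule, then either stops for
    futility or recruits to the final target and analyzes as a classical
    trial at the unadjusted level.
    """
    plan.validate()
    true_scenario.require_valid()
    rng = _rng(seed)
    n_interim = plan.interim_n()
    interim = simulate_cohort(true_scenario, n_interim, rng)
    decision = interim_reestimate(plan, interim)
    if decision.action == "stop_futility":
        return AdaptiveTrialOutcome(
            decision=decision, trial=None, stopped_for_futility=True, final_n=n_interim
        )
    n_final = decision.n_final_target
    if n_final > n_interim:
        extra = simulate_cohort(true_scenario, n_final - n_interim, rng)
        extra["id"] += n_interim
        cohort = pd.concat([interim, extra], ignore_index=True)
    else:
        cohort = interim
    trial = run_classical(true_scenario, cohort, rng)
    return AdaptiveTrialOutcome(
        decision=decision, trial=trial, stopped_for_futility=False, final_n=len(cohort)
    )


def operating_characteristics(
    true_scenario: ScenarioModel,
    plan: AdaptivePlan,
    n_reps: int,
    seed: int,
) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics of the adaptive procedure.

    Runs ``n_reps`` adaptive trials on the fast array core; the
    re-estimated n is cached per interim positive count (the estimate
    takes only n_interim + 1 values), so large replicate counts stay
    cheap. Deterministic under ``seed``.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps!r}")
    plan.validate()
    true_scenario.require_valid()
    rng = _rng(seed)
    n_interim = plan.interim_n()
    n_init = plan.initial_sample_size().n_total
    cache: Dict[int, int] = {}
    rejected = np.zeros(n_reps, dtype=bool)
    stopped = np.zeros(n_reps, dtype=bool)
    final_n = np.empty(n_reps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n_reps):
            d, r_a, r_b = _cohort_arrays(true_scenario, n_interim, rng)
            k = int(d.sum())
            if k not in cache:
                cache[k] = _reestimate_n(plan, k / n_interim)
            n_re = cache[k]
            if n_re > plan.n_max:
                stopped[i] = True
                final_n[i] = n_interim
                continue
            if n_re <= n_init:
                n_target = max(n_re if plan.allow_decrease else n_init, n_interim)
            else:
                n_target = n_re
            if n_target > n_interim:
                d2, ra2, rb2 = _cohort_arrays(true_scenario, n_target - n_interim, rng)
                d = np.concatenate([d, d2])
                r_a = np.concatenate([r_a, ra2])
                r_b = np.concatenate([r_b, rb2])
            to_a = rng.random(len(d)) < 0.5
            r = np.where(to_a, r_a, r_b)
            m_idx = true_scenario.link.management_index(r)
            y = _draw_outcomes(true_scenario, m_idx, r_a, r_b, d, rng)
            try:
                _, p, _ = _analyze(true_scenario, y, to_a)
            except DegenerateAnalysisError:
                p = float("nan")
            rejected[i] = p <= plan.alpha
            final_n[i] = len(d)
    rate = float(rejected.mean())
    n_completed = int((~stopped).sum())
    completed_rate = float(rejected[~stopped].mean()) if n_completed else float("nan")
    qs = np.quantile(final_n, [0.05, 0.25, 0.5, 0.75, 0.95])
    return OperatingCharacteristics(
        rejection_rate=rate,
        mc_standard_error=float(np.sqrt(rate * (1.0 - rate) / n_reps)),
        completed_rejection_rate=completed_rate,
        futility_rate=float(stopped.mean()),
        mean_final_n=float(final_n.mean()),
        final_n_quantiles={f"q{int(100*q):02d}": float(v) for q, v in zip([0.05, 0.25, 0.5, 0.75, 0.95], qs)},
        n_reps=n_reps,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        alpha=plan.alpha,
    )
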