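"""Patient-level Monte-Carlo engine for randomized test-treatment designs.

Four design executors are provided, mirroring the trial flows:

* ``classical`` — patients randomized 1:1 to have test A or B applied;
  only the assigned test's result is observed and followed.
* ``discordant`` — both tests applied to everyone; concordant patients
  are managed per the (shared) result and excluded from the primary
  analysis; discordant patients are randomized 1:1 to follow A or B.
* ``random_disclosure`` — both tests applied; one result disclosed at
  random and followed; analyzed either like the classical design or
  restricted to the discordant subgroup.
* ``single_test_disclosure`` — one test only; patients randomized to
  disclosure (management follows the result) or non-disclosure (all
  receive management I).

Outcomes are always generated conditional on *both* latent test results
and the true disease status — an unmeasured result may carry prognostic
value — and the unmeasured result is stored but flagged unobserved.

Binary analyses use the Pearson chi-squared test of two proportions
without continuity correction (the score test matching the sample-size
formula family); continuous analyses use Welch's two-sample t test.

Trial datasets are pandas DataFrames with columns::

    id             int      patient index within the trial
    d              int8     true disease status (1 diseased, 0 not)
    r_a, r_b       int8     test results (1 positive); -1 if the test
                            was never applied in this design
    r_a_observed,
    r_b_observed   bool     whether the result was revealed/used
    arm            str      design-specific randomized arm label
    followed_test  str      "A", "B" or "none"
    management     str      "I" or "II"
    y              number   outcome (0/1 binary, real continuous)
    analyzed       bool     included in the primary analysis
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .scenario import MANAGEMENTS, ScenarioModel, joint_result_probs

__all__ = [
    "DESIGNS",
    "PatientRecord",
    "TrialResult",
    "SimulationSummary",
    "DegenerateAnalysisError",
    "simulate_cohort",
    "run_classical",
    "run_discordant",
    "run_random_disclosure",
    "run_single_test_disclosure",
    "run_design",
    "estimate_power",
    "chi2_two_proportions",
]

DESIGNS = ("classical", "discordant", "random_disclosure", "single_test_disclosure")


class DegenerateAnalysisError(RuntimeError):
    """Raised when a trial cannot be analyzed (empty arm, no discordance)."""


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient (a typed view of one trial-dataset row)."""

    id: int
    d: int
    r_a: int
    r_b: int
    arm: str
    followed_test: str
    management: str
    y: float


@dataclass
class TrialResult:
    """One simulated, analyzed trial."""

    dataset: pd.DataFrame
    test_statistic: float
    p_value: float
    estimate: float
    n_analyzed: int
    design: str


@dataclass(frozen=True)
class SimulationSummary:
    """Monte-Carlo rejection-rate summary across replicated trials."""

    rejection_rate: float
    mc_standard_error: float
    n_reps: int
    seed: int
    design: str
    alpha: float
    mean_estimate: float

    @classmethod
    def from_rejections(cls, rejected: np.ndarray, estimates: np.ndarray, seed, design, alpha):
        r = float(np.mean(rejected))
        return cls(
            rejection_rate=r,
            mc_standard_error=float(np.sqrt(r * (1.0 - r) / len(rejected))),
            n_reps=len(rejected),
            seed=int(seed),
            design=design,
            alpha=alpha,
            mean_estimate=float(np.nanmean(estimates)) if len(estimates) else float("nan"),
        )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# array core — all randomness flows through the single Generator passed in
# ---------------------------------------------------------------------------

def _cohort_arrays(scenario: ScenarioModel, n: int, rng) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (d, r_a, r_b) for n patients: d ~ Bernoulli(prevalence), the
    result pair from the joint conditional distribution of its stratum."""
    prev = scenario.population.prevalence
    d = (rng.random(n) < prev).astype(np.int8)
    # cumulative cell probabilities per stratum, cell order (--, -+, +-, ++)
    cums = np.empty((2, 4))
    for dd in (0, 1):
        joint = joint_result_probs(scenario.tests, dd)
        cells = np.array([joint[0, 0], joint[0, 1], joint[1, 0], joint[1, 1]])
        cums[dd] = np.cumsum(cells)
    u = rng.random(n)
    idx = (u[:, None] > cums[d]).sum(axis=1)
    r_a = (idx >> 1).astype(np.int8)
    r_b = (idx & 1).astype(np.int8)
    return d, r_a, r_b


def _draw_outcomes(scenario: ScenarioModel, m_idx, r_a, r_b, d, rng) -> np.ndarray:
    """Outcomes conditional on (management, t_A, t_B, d)."""
    e = scenario.outcomes.e_array
    mean = e[m_idx, r_a, r_b, d]
    if scenario.outcomes.outcome_scale == "binary":
        return (rng.random(len(mean)) < mean).astype(np.int8)
    return rng.normal(mean, scenario.outcomes.sd)


def _analyze_binary(y, in_a) -> Tuple[float, float, float]:
    """Pearson chi-squared (score) test of two proportions, no continuity
    correction. Returns (statistic, p, p_hat_A - p_hat_B)."""
    n1 = int(in_a.sum())
    n2 = len(in_a) - n1
    if n1 == 0 or n2 == 0:
        raise DegenerateAnalysisError("one analysis arm is empty")
    x1 = float(y[in_a].sum())
    x2 = float(y[~in_a].sum())
    return chi2_two_proportions(x1, n1, x2, n2)


def chi2_two_proportions(x1: float, n1: int, x2: float, n2: int) -> Tuple[float, float, float]:
    """Chi-squared test of two independent proportions from 2x2 counts.

    Pearson statistic without continuity correction, identical to the
    squared score z statistic with pooled variance. Returns
    ``(statistic, p_value, p1_hat - p2_hat)``.
    """
    p1, p2 = x1 / n1, x2 / n2
    pbar = (x1 + x2) / (n1 + n2)
    var = pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2)
    if var == 0.0:
        return 0.0, 1.0, p1 - p2
    stat = (p1 - p2) ** 2 / var
    return float(stat), float(stats.chi2.sf(stat, 1)), float(p1 - p2)


def _analyze_continuous(y, in_a) -> Tuple[float, float, float]:
    """Welch two-sample t test. Returns (t, p, mean_A - mean_B)."""
    n1 = int(in_a.sum())
    n2 = len(in_a) - n1
    if n1 < 2 or n2 < 2:
        raise DegenerateAnalysisError("analysis arm too small for a t test")
    y1, y2 = y[in_a], y[~in_a]
    m1, m2 = float(y1.mean()), float(y2.mean())
    v1 = float(y1.var(ddof=1)) / n1
    v2 = float(y2.var(ddof=1)) / n2
    se2 = v1 + v2
    if se2 == 0.0:
        return 0.0, 1.0, m1 - m2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(2.0 * stats.t.sf(abs(t), df)), m1 - m2


def _analyze(scenario: ScenarioModel, y, in_a) -> Tuple[float, float, float]:
    if scenario.outcomes.outcome_scale == "binary":
        return _analyze_binary(y, in_a)
    return _analyze_continuous(y, in_a)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_cohort(scenario: ScenarioModel, n: int, seed) -> pd.DataFrame:
    """Pre-randomization cohort: disease status and both latent test
    results for ``n`` patients, reproducible under a fixed seed."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n!r}")
    scenario.require_valid()
    d, r_a, r_b = _cohort_arrays(scenario, n, _rng(seed))
    return pd.DataFrame({"id": np.arange(n), "d": d, "r_a": r_a, "r_b": r_b})


def _base_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    df = cohort[["id", "d", "r_a", "r_b"]].copy()
    df["r_a_observed"] = False
    df["r_b_observed"] = False
    return df


def _finish(df, y, analyzed, scenario, design, in_a) -> TrialResult:
    df["y"] = y
    df["analyzed"] = analyzed
    stat, p, est = _analyze(scenario, y[analyzed], in_a)
    return TrialResult(
        dataset=df,
        test_statistic=stat,
        p_value=p,
        estimate=est,
        n_analyzed=int(analyzed.sum()),
        design=design,
    )


def run_classical(scenario: ScenarioModel, cohort: pd.DataFrame, seed) -> TrialResult:
    """Classical test-treatment RCT: 1:1 randomization to test A or B;
    the assigned test's result drives management; arms compared on Y."""
    scenario.require_valid()
    rng = _rng(seed)
    df = _base_frame(cohort)
    n = len(df)
    to_a = rng.random(n) < 0.5
    r = np.where(to_a, df["r_a"].to_numpy(), df["r_b"].to_numpy())
    m_idx = scenario.link.management_index(r)
    y = _draw_outcomes(scenario, m_idx, df["r_a"].to_numpy(), df["r_b"].to_numpy(), df["d"].to_numpy(), rng)
    df["arm"] = np.where(to_a, "A", "B")
    df["followed_test"] = df["arm"]
    df["management"] = np.asarray(MANAGEMENTS)[m_idx]
    df["r_a_observed"] = to_a
    df["r_b_observed"] = ~to_a
    analyzed = np.ones(n, dtype=bool)
    return _finish(df, y, analyzed, scenario, "classical", to_a)


def run_discordant(scenario: ScenarioModel, cohort: pd.DataFrame, seed) -> TrialResult:
    """Discordant-pairs design: both tests applied; concordant patients
    managed per the shared result (simulated but excluded from the
    primary analysis); discordant patients randomized to follow A or B."""
    scenario.require_valid()
    rng = _rng(seed)
    df = _base_frame(cohort)
    n = len(df)
    r_a = df["r_a"].to_numpy()
    r_b = df["r_b"].to_numpy()
    disc = r_a != r_b
    if not disc.any():
        raise DegenerateAnalysisError("no discordant patients: nothing to randomize")
    to_a = rng.random(n) < 0.5  # drawn for everyone, meaningful only when discordant
    followed = np.where(disc, np.where(to_a, "A", "B"), "none")
    r = np.where(disc, np.where(to_a, r_a, r_b), r_a)  # concordant: r_a == r_b
    m_idx = scenario.link.management_index(r)
    y = _draw_outcomes(scenario, m_idx, r_a, r_b, df["d"].to_numpy(), rng)
    df["arm"] = np.where(disc, np.where(to_a, "A", "B"), "concordant")
    df["followed_test"] = followed
    df["management"] = np.asarray(MANAGEMENTS)[m_idx]
    df["r_a_observed"] = True
    df["r_b_observed"] = True
    return _finish(df, y, disc, scenario, "discordant", to_a[disc])


def run_random_disclosure(
    scenario: ScenarioModel, cohort: pd.DataFrame, seed, analysis: str = "classical"
) -> TrialResult:
    """Random-disclosure design: both tests applied, one result revealed
    at random and followed. ``analysis`` is ``"classical"`` (all patients
    by disclosed arm) or ``"discordant_subgroup"``."""
    if analysis not in ("classical", "discordant_subgroup"):
        raise ValueError(f"unknown analysis {analysis!r}")
    scenario.require_valid()
    rng = _rng(seed)
    df = _base_frame(cohort)
    n = len(df)
    r_a = df["r_a"].to_numpy()
    r_b = df["r_b"].to_numpy()
    to_a = rng.random(n) < 0.5
    r = np.where(to_a, r_a, r_b)
    m_idx = scenario.link.management_index(r)
    y = _draw_outcomes(scenario, m_idx, r_a, r_b, df["d"].to_numpy(), rng)
    df["arm"] = np.where(to_a, "A", "B")
    df["followed_test"] = df["arm"]
    df["management"] = np.asarray(MANAGEMENTS)[m_idx]
    df["r_a_observed"] = to_a  # both performed, only one revealed
    df["r_b_observed"] = ~to_a
    if analysis == "classical":
        analyzed = np.ones(n, dtype=bool)
    else:
        analyzed = r_a != r_b
        if not analyzed.any():
            raise DegenerateAnalysisError("no discordant patients in the subgroup analysis")
    return _finish(df, y, analyzed, scenario, "random_disclosure", to_a[analyzed])


def run_single_test_disclosure(scenario: ScenarioModel, cohort: pd.DataFrame, seed) -> TrialResult:
    """Single-test disclosure variant: only test A is used. Disclosure arm
    follows the link rule; in the non-disclosure arm every patient
    receives management I (positives and non-disclosed alike). The
    estimate is mean(disclosure) - mean(non-disclosure)."""
    scenario.require_valid()
    rng = _rng(seed)
    df = _base_frame(cohort)
    n = len(df)
    r_a = df["r_a"].to_numpy()
    disclose = rng.random(n) < 0.5
    m_idx = np.where(
        disclose,
        scenario.link.management_index(r_a),
        MANAGEMENTS.index("I"),
    )
    y = _draw_outcomes(scenario, m_idx, r_a, df["r_b"].to_numpy(), df["d"].to_numpy(), rng)
    df["arm"] = np.where(disclose, "disclosure", "non_disclosure")
    df["followed_test"] = np.where(disclose, "A", "none")
    df["management"] = np.asarray(MANAGEMENTS)[m_idx]
    df["r_a_observed"] = disclose
    analyzed = np.ones(n, dtype=bool)
    return _finish(df, y, analyzed, scenario, "single_test_disclosure", disclose)


_RUNNERS = {
    "classical": run_classical,
    "discordant": run_discordant,
    "random_disclosure": run_random_disclosure,
    "single_test_disclosure": run_single_test_disclosure,
}


def run_design(scenario: ScenarioModel, design: str, cohort: pd.DataFrame, seed, **kwargs) -> TrialResult:
    """Dispatch to the executor for ``design`` (see :data:`DESIGNS`)."""
    if design not in _RUNNERS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    return _RUNNERS[design](scenario, cohort, seed, **kwargs)


# ---------------------------------------------------------------------------
# Monte-Carlo operating characteristics
# ---------------------------------------------------------------------------

def _one_rep_pvalue(scenario, design, n, rng, analysis) -> Tuple[float, float]:
    """One replicate on the array core (no DataFrame); returns (p, estimate).
    Degenerate replicates (no discordance, empty arm) yield p = nan."""
    d, r_a, r_b = _cohort_arrays(scenario, n, rng)
    if design == "classical" or design == "random_disclosure":
        to_a = rng.random(n) < 0.5
        r = np.where(to_a, r_a, r_b)
        m_idx = scenario.link.management_index(r)
        y = _draw_outcomes(scenario, m_idx, r_a, r_b, d, rng)
        if design == "random_disclosure" and analysis == "discordant_subgroup":
            keep = r_a != r_b
            y, to_a = y[keep], to_a[keep]
    elif design == "discordant":
        disc = r_a != r_b
        to_a = rng.random(n) < 0.5
        r = np.where(disc, np.where(to_a, r_a, r_b), r_a)
        m_idx = scenario.link.management_index(r)
        y = _draw_outcomes(scenario, m_idx, r_a, r_b, d, rng)
        y, to_a = y[disc], to_a[disc]
    elif design == "single_test_disclosure":
        disclose = rng.random(n) < 0.5
        m_idx = np.where(disclose, scenario.link.management_index(r_a), MANAGEMENTS.index("I"))
        y = _draw_outcomes(scenario, m_idx, r_a, r_b, d, rng)
        to_a = disclose
    else:
        raise ValueError(f"unknown design {design!r}")
    try:
        _, p, est = _analyze(scenario, y, to_a)
    except DegenerateAnalysisError:
        return float("nan"), float("nan")
    return p, est


def estimate_power(
    scenario: ScenarioModel,
    design: str,
    n: int,
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
    analysis: str = "classical",
) -> SimulationSummary:
    """Monte-Carlo rejection rate of a design at cohort size ``n``.

    ``n`` is the number of patients entering the design flow: the number
    randomized in the classical design, the screened cohort (both tests
    applied) in the discordant and disclosure designs. Replicates whose
    analysis is degenerate count as non-rejections. Deterministic under
    ``seed``.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps!r}")
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    scenario.require_valid()
    rng = _rng(seed)
    pvals = np.empty(n_reps)
    ests = np.empty(n_reps)
    for i in range(n_reps):
        pvals[i], ests[i] = _one_rep_pvalue(scenario, design, n, rng, analysis)
    rejected = pvals <= alpha  # nan compares False -> non-rejection
    return SimulationSummary.from_rejections(
        rejected, ests, seed if not isinstance(seed, np.random.Generator) else -1, design, alpha
    )
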