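"""Scenario model for randomized test-treatment trials.

A scenario bundles the full generative truth needed to plan or simulate a
trial comparing two binary diagnostic tests A and B, each linked to one of
two management strategies (I, II):

* the disease prevalence P(D=+),
* the paired accuracy model P(R_A, R_B | D) — per-test sensitivity and
  specificity plus a conditional covariance of the two positive-result
  indicators within each disease stratum,
* the deterministic link rule m(·) from test result to management
  (default: positives -> I, negatives -> II),
* the joint outcome model e(m, t_A, t_B, d) giving the expected outcome of
  a patient with test results (t_A, t_B), disease status d, managed by m.

Planning-level views (the per-test outcome table mu^tau_{mtd}, move
effects) are derived from this canonical representation, never stored
independently, so the unpaired and paired effect-size expansions are
consistent by construction.

Conventions
-----------
Test results and disease status are coded ``1`` for positive/diseased and
``0`` for negative/non-diseased throughout the numeric API; the symbols
"+" / "-" are used in serialized configs. Managements are the strings
``"I"`` and ``"II"`` (internally indexed 0 and 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np

__all__ = [
    "MANAGEMENTS",
    "TEST_LABELS",
    "DiseasePopulation",
    "TestAccuracy",
    "PairedTestModel",
    "LinkRule",
    "JointOutcomeModel",
    "UnpairedOutcomeTable",
    "MoveEffects",
    "ScenarioModel",
    "ScenarioValidationError",
    "joint_result_probs",
    "frechet_bounds",
    "mu_from_joint",
    "validate_scenario",
]

MANAGEMENTS: Tuple[str, str] = ("I", "II")
TEST_LABELS: Tuple[str, str] = ("A", "B")

_SUM_TOL = 1e-12  # absolute tolerance for probability sum-to-one checks
_CELL_TOL = 1e-12  # tolerance on individual cell probabilities


class ScenarioValidationError(ValueError):
    """Raised when a scenario (or component) violates its invariants.

    Carries the full list of violations in ``violations``.
    """

    def __init__(self, violations: List[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class DiseasePopulation:
    """Target population, characterized by its disease prevalence P(D=+)."""

    prevalence: float

    def validate(self) -> List[str]:
        if not (0.0 <= self.prevalence <= 1.0):
            return [f"prevalence must lie in [0, 1], got {self.prevalence!r}"]
        return []

    def prob(self, diseased: int) -> float:
        """P(D=d) for d coded 1 (diseased) or 0 (non-diseased)."""
        return self.prevalence if diseased else 1.0 - self.prevalence


@dataclass(frozen=True)
class TestAccuracy:
    """Sensitivity P(R=+|D=+) and specificity P(R=-|D=-) of one test."""

    sensitivity: float
    specificity: float

    def validate(self, label: str = "test") -> List[str]:
        out = []
        if not (0.0 <= self.sensitivity <= 1.0):
            out.append(f"{label}: sensitivity must lie in [0, 1], got {self.sensitivity!r}")
        if not (0.0 <= self.specificity <= 1.0):
            out.append(f"{label}: specificity must lie in [0, 1], got {self.specificity!r}")
        return out

    def positive_prob(self, diseased: int) -> float:
        """P(R=+|D=d): sensitivity in the diseased stratum, false-positive
        rate 1-specificity in the non-diseased stratum."""
        return self.sensitivity if diseased else 1.0 - self.specificity


def frechet_bounds(p_a: float, p_b: float) -> Tuple[float, float]:
    """Feasible range of cov(1{R_A=+}, 1{R_B=+}) given the two marginal
    positive probabilities, from the Fréchet–Hoeffding bounds on the
    (+,+) cell: max(0, p_a+p_b-1) <= P(++) <= min(p_a, p_b)."""
    lo = max(0.0, p_a + p_b - 1.0) - p_a * p_b
    hi = min(p_a, p_b) - p_a * p_b
    return lo, hi


@dataclass(frozen=True)
class PairedTestModel:
    """Joint accuracy model for the two tests.

    Within each disease stratum d the joint distribution of the two binary
    results is fixed by the marginals (sensitivity / 1-specificity) plus
    the conditional covariance of the positive-result indicators:

        P(R_A=+, R_B=+ | D=d) = p_A(d) p_B(d) + cov_d

    with the remaining three cells following by marginal consistency.
    ``cov_diseased = cov_nondiseased = 0`` recovers conditional
    independence. Positive covariance makes concordant results more
    frequent; the maximally negative covariance maximizes discordance.
    """

    accuracy_a: TestAccuracy
    accuracy_b: TestAccuracy
    cov_diseased: float = 0.0
    cov_nondiseased: float = 0.0

    @classmethod
    def from_correlation(
        cls,
        accuracy_a: TestAccuracy,
        accuracy_b: TestAccuracy,
        corr_diseased: float = 0.0,
        corr_nondiseased: float = 0.0,
    ) -> "PairedTestModel":
        """Build from conditional Pearson correlations of the positive
        indicators, converting via cov = rho * sqrt(p_a q_a p_b q_b)."""
        covs = []
        for d, rho in ((1, corr_diseased), (0, corr_nondiseased)):
            pa = accuracy_a.positive_prob(d)
            pb = accuracy_b.positive_prob(d)
            covs.append(rho * np.sqrt(pa * (1 - pa) * pb * (1 - pb)))
        return cls(accuracy_a, accuracy_b, cov_diseased=covs[0], cov_nondiseased=covs[1])

    def accuracy(self, label: str) -> TestAccuracy:
        if label == "A":
            return self.accuracy_a
        if label == "B":
            return self.accuracy_b
        raise KeyError(f"unknown test label {label!r}; expected 'A' or 'B'")

    def cov(self, diseased: int) -> float:
        return self.cov_diseased if diseased else self.cov_nondiseased

    def validate(self) -> List[str]:
        out = self.accuracy_a.validate("test A") + self.accuracy_b.validate("test B")
        if out:
            return out
        for diseased, name in ((1, "diseased"), (0, "non-diseased")):
            cells = _joint_cells(self, diseased)
            for (ta, tb), p in cells.items():
                if p < -_CELL_TOL or p > 1.0 + _CELL_TOL:
                    sym = {1: "+", 0: "-"}
                    out.append(
                        f"cov_{name.replace('-', '')}: joint cell "
                        f"P(R_A={sym[ta]}, R_B={sym[tb]} | D={'+' if diseased else '-'})"
                        f" = {p:.6g} lies outside [0, 1]"
                    )
        return out


def _joint_cells(tests: PairedTestModel, diseased: int) -> Dict[Tuple[int, int], float]:
    pa = tests.accuracy_a.positive_prob(diseased)
    pb = tests.accuracy_b.positive_prob(diseased)
    c = tests.cov(diseased)
    p11 = pa * pb + c
    return {
        (1, 1): p11,
        (1, 0): pa - p11,
        (0, 1): pb - p11,
        (0, 0): 1.0 - pa - pb + p11,
    }


def joint_result_probs(tests: PairedTestModel, diseased: int) -> np.ndarray:
    """Joint distribution of the two test results within a disease stratum.

    Parameters
    ----------
    tests
        Paired accuracy model.
    diseased
        Disease stratum, ``1`` (diseased) or ``0`` (non-diseased).

    Returns
    -------
    numpy.ndarray
        2x2 table ``P[t_a, t_b]`` = P(R_A=t_a, R_B=t_b | D=d) with index
        ``1`` meaning a positive result. Cells sum to one and reproduce
        the marginal sensitivity/specificity exactly.

    Raises
    ------
    ScenarioValidationError
        If the covariance for this stratum lies outside the Fréchet
        bounds, naming the violated cell.
    """
    violations = tests.validate()
    if violations:
        raise ScenarioValidationError(violations)
    cells = _joint_cells(tests, diseased)
    table = np.zeros((2, 2))
    for (ta, tb), p in cells.items():
        table[ta, tb] = p
    # clip away representation noise; invariants guarantee near-[0,1]
    return np.clip(table, 0.0, 1.0)


@dataclass(frozen=True)
class LinkRule:
    """Deterministic mapping from a test result to a management strategy.

    Default is the standard rule: positive -> I (the more aggressive
    strategy, intended for the diseased) and negative -> II (standard
    care, intended for the non-diseased).
    """

    positive: str = "I"
    negative: str = "II"

    def validate(self) -> List[str]:
        out = []
        for name, m in (("positive", self.positive), ("negative", self.negative)):
            if m not in MANAGEMENTS:
                out.append(f"link rule maps {name} result to unknown management {m!r}")
        return out

    def management(self, result: int) -> str:
        """Management for a result coded 1 (positive) / 0 (negative)."""
        return self.positive if result else self.negative

    def management_index(self, result) -> np.ndarray:
        """Vectorized management index (0 for I, 1 for II) of result codes."""
        pos_idx = MANAGEMENTS.index(self.positive)
        neg_idx = MANAGEMENTS.index(self.negative)
        return np.where(np.asarray(result) == 1, pos_idx, neg_idx)


class JointOutcomeModel:
    """Expected outcome e(m, t_A, t_B, d) over all 16 strata.

    The table conditions on both test results because a test result can
    carry prognostic value beyond the true disease state; planning-level
    per-test tables are obtained by marginalizing over the unobserved
    result (see :func:`mu_from_joint`).

    Parameters
    ----------
    outcome_scale : {"binary", "continuous"}
        Binary outcomes are Bernoulli with success probability ``e``;
        continuous outcomes are Normal(e, sd) with a common residual
        standard deviation.
    e_table : mapping
        ``(m, t_a, t_b, d) -> expected outcome`` with ``m`` in
        {"I", "II"} and ``t_a, t_b, d`` in {1, 0} (or "+"/"-"). Must be
        total over all 16 combinations.
    sd : float, optional
        Residual standard deviation; required (and > 0) on the
        continuous scale, ignored on the binary scale.
    """

    def __init__(self, outcome_scale: str, e_table: Mapping, sd: float | None = None):
        self.outcome_scale = outcome_scale
        self.sd = sd
        self._e = np.full((2, 2, 2, 2), np.nan)  # [m_idx, t_a, t_b, d]
        for key, value in e_table.items():
            m, ta, tb, d = key
            self._e[MANAGEMENTS.index(m), _code(ta), _code(tb), _code(d)] = float(value)

    # -- constructors ---------------------------------------------------
    @classmethod
    def constant(cls, value: float, outcome_scale: str = "binary", sd: float | None = None):
        """Outcome table with the same expected outcome in every stratum."""
        tab = {(m, ta, tb, d): value for m in MANAGEMENTS for ta in (1, 0) for tb in (1, 0) for d in (1, 0)}
        return cls(outcome_scale, tab, sd=sd)

    @classmethod
    def from_management_disease(
        cls, e_md: Mapping[Tuple[str, object], float], outcome_scale: str = "binary", sd: float | None = None
    ):
        """Build a table where the outcome depends only on the management
        received and the true disease status, i.e. the test results carry
        no prognostic value. ``e_md`` maps ("I"|"II", d) -> value."""
        tab = {}
        for m in MANAGEMENTS:
            for d in (1, 0):
                v = e_md.get((m, d), e_md.get((m, "+" if d else "-")))
                if v is None:
                    raise KeyError(f"from_management_disease: missing entry for ({m}, {d})")
                for ta in (1, 0):
                    for tb in (1, 0):
                        tab[(m, ta, tb, d)] = v
        return cls(outcome_scale, tab, sd=sd)

    # -- access ---------------------------------------------------------
    @property
    def e_array(self) -> np.ndarray:
        """Read-only (2,2,2,2) array indexed [management, t_A, t_B, d],
        management 0 = I, 1 = II; result/disease 1 = positive."""
        return self._e

    def expected_outcome(self, m: str, t_a, t_b, d) -> float:
        return float(self._e[MANAGEMENTS.index(m), _code(t_a), _code(t_b), _code(d)])

    def as_table(self) -> Dict[Tuple[str, int, int, int], float]:
        return {
            (m, ta, tb, d): float(self._e[mi, ta, tb, d])
            for mi, m in enumerate(MANAGEMENTS)
            for ta in (1, 0)
            for tb in (1, 0)
            for d in (1, 0)
        }

    def validate(self) -> List[str]:
        out = []
        if self.outcome_scale not in ("binary", "continuous"):
            out.append(f"outcome_scale must be 'binary' or 'continuous', got {self.outcome_scale!r}")
            return out
        if np.isnan(self._e).any():
            missing = int(np.isnan(self._e).sum())
            out.append(f"outcome table is not total: {missing} of 16 strata missing")
            return out
        if self.outcome_scale == "binary":
            if (self._e < 0).any() or (self._e > 1).any():
                bad = np.argwhere((self._e < 0) | (self._e > 1))[0]
                out.append(
                    "binary outcome table entry outside [0, 1] at "
                    f"(m={MANAGEMENTS[bad[0]]}, t_A={_sym(bad[1])}, t_B={_sym(bad[2])}, d={_sym(bad[3])})"
                )
        else:
            if self.sd is None or not self.sd > 0:
                out.append(f"continuous outcome scale requires sd > 0, got {self.sd!r}")
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, JointOutcomeModel):
            return NotImplemented
        return (
            self.outcome_scale == other.outcome_scale
            and (self.sd == other.sd or (self.sd is None and other.sd is None))
            and np.array_equal(self._e, other._e, equal_nan=True)
        )

    def __repr__(self) -> str:
        return f"JointOutcomeModel(scale={self.outcome_scale!r}, sd={self.sd!r})"


@dataclass(frozen=True)
class UnpairedOutcomeTable:
    """Planning-level per-test outcome table mu^tau_{mtd} = E(Y | M=m,
    R_tau=t, D=d), a derived view of the joint outcome model.

    Cells conditioning on a zero-probability result (e.g. a negative
    result of a perfect test in the diseased stratum) are undefined and
    raise when accessed."""

    mu: Mapping[Tuple[str, str, int, int], float]  # (tau, m, t, d) -> value

    def value(self, tau: str, m: str, t, d) -> float:
        v = self.mu[(tau, m, _code(t), _code(d))]
        if v != v:  # NaN marks an undefined conditional
            raise ScenarioValidationError(
                [
                    f"mu^{tau}_{{m={m}, t={_sym(_code(t))}, d={_sym(_code(d))}}} is undefined: "
                    f"P(R_{tau}={_sym(_code(t))} | D={_sym(_code(d))}) = 0"
                ]
            )
        return v


@dataclass(frozen=True)
class MoveEffects:
    """Elicited expected outcome differences for the four reclassification
    moves when strategy B is replaced by strategy A in one patient.

    Under the default sign-symmetry assumption the two reverse moves are
    the negations of the elicited ones: D(TN->FP) = -D(FP->TN) and
    D(TP->FN) = -D(FN->TP); both can be overridden.
    """

    delta_fp_to_tn: float
    delta_fn_to_tp: float
    delta_tn_to_fp: float | None = None
    delta_tp_to_fn: float | None = None

    @property
    def tn_to_fp(self) -> float:
        return -self.delta_fp_to_tn if self.delta_tn_to_fp is None else self.delta_tn_to_fp

    @property
    def tp_to_fn(self) -> float:
        return -self.delta_fn_to_tp if self.delta_tp_to_fn is None else self.delta_tp_to_fn


@dataclass(frozen=True)
class ScenarioModel:
    """Full generative truth for one trial-planning scenario."""

    population: DiseasePopulation
    tests: PairedTestModel
    outcomes: JointOutcomeModel
    link: LinkRule = field(default_factory=LinkRule)

    def validate(self) -> List[str]:
        return validate_scenario(self)

    def require_valid(self) -> "ScenarioModel":
        violations = self.validate()
        if violations:
            raise ScenarioValidationError(violations)
        return self

    def with_prevalence(self, prevalence: float) -> "ScenarioModel":
        """Copy of the scenario with the prevalence replaced, everything
        else (accuracy, dependence, outcome tables) held fixed."""
        return dataclasses.replace(self, population=DiseasePopulation(prevalence))


def validate_scenario(scenario: ScenarioModel) -> List[str]:
    """Collect every violated invariant of a scenario.

    Violations are returned as human-readable strings (empty list iff the
    scenario is valid); nothing is raised, so callers can report all
    problems at once.
    """
    out: List[str] = []
    out += scenario.population.validate()
    out += scenario.tests.validate()
    out += scenario.link.validate()
    out += scenario.outcomes.validate()
    return out


def mu_from_joint(scenario: ScenarioModel, tau: str) -> UnpairedOutcomeTable:
    """Derive the per-test planning table mu^tau_{mtd} for test ``tau``.

    Marginalizes the joint outcome table over the unobserved other test's
    result, weighting by its conditional distribution given R_tau=t and
    D=d:

        mu^tau_{mtd} = sum_{t'} e(m, ..., d) P(other = t' | R_tau=t, D=d).

    If ``e`` does not depend on the other test's result, mu equals e.

    Raises
    ------
    ScenarioValidationError
        If P(R_tau=t | D=d) = 0 for a requested cell (the conditional is
        undefined there).
    """
    if tau not in TEST_LABELS:
        raise KeyError(f"unknown test label {tau!r}; expected 'A' or 'B'")
    e = scenario.outcomes.e_array
    mu: Dict[Tuple[str, str, int, int], float] = {}
    for d in (1, 0):
        joint = joint_result_probs(scenario.tests, d)  # [t_a, t_b]
        for t in (1, 0):
            if tau == "A":
                marginal = joint[t, :].sum()
                cond = joint[t, :]
            else:
                marginal = joint[:, t].sum()
                cond = joint[:, t]
            for mi, m in enumerate(MANAGEMENTS):
                if marginal <= 0.0:
                    # undefined conditional; raises only if the cell is read
                    mu[(tau, m, t, d)] = float("nan")
                    continue
                if tau == "A":
                    vals = e[mi, t, :, d]
                else:
                    vals = e[mi, :, t, d]
                mu[(tau, m, t, d)] = float(np.dot(vals, cond) / marginal)
    return UnpairedOutcomeTable(mu=mu)


def _code(x) -> int:
    """Normalize a result/disease code to int 1 (positive) / 0 (negative)."""
    if x in (1, True, "+", "pos", "positive"):
        return 1
    if x in (0, False, "-", "neg", "negative"):
        return 0
    raise ValueError(f"cannot interpret {x!r} as a binary result/disease code")


def _sym(x: int) -> str:
    return "+" if x else "-"
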