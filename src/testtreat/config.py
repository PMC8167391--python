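"""Scenario (de)serialization and report writing.

Scenario configs are YAML (JSON is a YAML subset and parses too) with the
schema documented in the README::

    population:
      prevalence: 0.3
    tests:
      A: {sensitivity: 0.9, specificity: 0.8}
      B: {sensitivity: 0.7, specificity: 0.9}
      covariance: {diseased: 0.0, non_diseased: 0.0}
    link: {positive: I, negative: II}
    outcomes:
      scale: binary          # or continuous (then sd is required)
      sd: null
      table:                 # 16 entries "management,t_A,t_B,d" -> value
        "I,+,+,+": 0.7
        ...

All probabilities are decimals, never percentages. Reports are JSON (or a
flat CSV row) carrying the package version, the seed, and a hash of the
serialized inputs; payloads contain no timestamps, so identical results
serialize byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Dict

import yaml

from . import __version__
from .scenario import (
    DiseasePopulation,
    JointOutcomeModel,
    LinkRule,
    PairedTestModel,
    ScenarioModel,
    ScenarioValidationError,
    TestAccuracy,
)

__all__ = [
    "scenario_to_dict",
    "scenario_from_dict",
    "load_scenario",
    "save_scenario",
    "write_report",
    "result_to_dict",
]

_SYM = {1: "+", 0: "-"}


def scenario_to_dict(scenario: ScenarioModel) -> Dict[str, Any]:
    """Serializable mapping for a scenario (inverse of
    :func:`scenario_from_dict`)."""
    table = {
        f"{m},{_SYM[ta]},{_SYM[tb]},{_SYM[d]}": v
        for (m, ta, tb, d), v in sorted(scenario.outcomes.as_table().items())
    }
    return {
        "population": {"prevalence": scenario.population.prevalence},
        "tests": {
            "A": {
                "sensitivity": scenario.tests.accuracy_a.sensitivity,
                "specificity": scenario.tests.accuracy_a.specificity,
            },
            "B": {
                "sensitivity": scenario.tests.accuracy_b.sensitivity,
                "specificity": scenario.tests.accuracy_b.specificity,
            },
            "covariance": {
                "diseased": scenario.tests.cov_diseased,
                "non_diseased": scenario.tests.cov_nondiseased,
            },
        },
        "link": {"positive": scenario.link.positive, "negative": scenario.link.negative},
        "outcomes": {
            "scale": scenario.outcomes.outcome_scale,
            "sd": scenario.outcomes.sd,
            "table": table,
        },
    }


def scenario_from_dict(data: Dict[str, Any]) -> ScenarioModel:
    """Parse and validate a scenario mapping; every violation is reported
    at once via :class:`ScenarioValidationError`."""
    try:
        pop = DiseasePopulation(float(data["population"]["prevalence"]))
        tdata = data["tests"]
        cov = tdata.get("covariance", {}) or {}
        tests = PairedTestModel(
            accuracy_a=TestAccuracy(
                float(tdata["A"]["sensitivity"]), float(tdata["A"]["specificity"])
            ),
            accuracy_b=TestAccuracy(
                float(tdata["B"]["sensitivity"]), float(tdata["B"]["specificity"])
            ),
            cov_diseased=float(cov.get("diseased", 0.0)),
            cov_nondiseased=float(cov.get("non_diseased", 0.0)),
        )
        ldata = data.get("link", {}) or {}
        link = LinkRule(
            positive=str(ldata.get("positive", "I")), negative=str(ldata.get("negative", "II"))
        )
        odata = data["outcomes"]
        table = {}
        for key, value in odata["table"].items():
            m, ta, tb, d = (part.strip() for part in str(key).split(","))
            table[(m, ta, tb, d)] = float(value)
        sd = odata.get("sd")
        outcomes = JointOutcomeModel(
            outcome_scale=str(odata["scale"]),
            e_table=table,
            sd=None if sd is None else float(sd),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ScenarioValidationError([f"malformed scenario config: {exc}"]) from exc
    scenario = ScenarioModel(population=pop, tests=tests, outcomes=outcomes, link=link)
    violations = scenario.validate()
    if violations:
        raise ScenarioValidationError(violations)
    return scenario


def load_scenario(path) -> ScenarioModel:
    """Load a validated scenario from a YAML/JSON config file."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ScenarioValidationError([f"cannot parse {path}: {exc}"]) from exc
    if not isinstance(data, dict):
        raise ScenarioValidationError([f"{path}: expected a mapping at the top level"])
    return scenario_from_dict(data)


def save_scenario(scenario: ScenarioModel, path) -> None:
    """Write a scenario config (round-trips exactly through
    :func:`load_scenario`)."""
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=True))


def result_to_dict(result: Any) -> Any:
    """Flatten any of the package's result dataclasses to plain data,
    dropping patient-level DataFrames (exported separately as CSV)."""
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        out = {}
        for f in dataclasses.fields(result):
            v = getattr(result, f.name)
            if v.__class__.__name__ == "DataFrame":
                continue
            out[f.name] = result_to_dict(v)
        return out
    if isinstance(result, dict):
        return {k: result_to_dict(v) for k, v in result.items()}
    if isinstance(result, (list, tuple)):
        return [result_to_dict(v) for v in result]
    if hasattr(result, "item"):  # numpy scalar
        return result.item()
    return result


def write_report(result: Any, path, format: str = "json", seed=None, inputs: Any = None) -> None:
    """Write a result artifact with provenance.

    The payload records the package version, the seed, and a SHA-256
    hash of the canonicalized inputs (when given); it contains no
    timestamps, so writing the same result twice yields byte-identical
    files.
    """
    payload = {
        "package": "testtreat",
        "version": __version__,
        "seed": seed,
        "input_hash": _hash_inputs(inputs),
        "result": result_to_dict(result),
    }
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    elif format == "csv":
        flat = _flatten(payload)
        header = ",".join(flat)
        row = ",".join("" if v is None else str(v) for v in flat.values())
        path.write_text(header + "\n" + row + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}; expected 'json' or 'csv'")


def _hash_inputs(inputs: Any) -> str | None:
    if inputs is None:
        return None
    canonical = json.dumps(result_to_dict(inputs), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _flatten(d: Dict[str, Any], prefix: str = "") -> Dict[str, Any]:
    out: Dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, prefix=key + "."))
        elif isinstance(v, (list, tuple)):
            out[key] = ";".join(str(x) for x in v)
        else:
            out[key] = v
    return out
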