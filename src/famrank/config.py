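"""Criteria configuration: defaults, YAML/JSON loading and saving.

The default configuration is the nine-sub-criterion weighting used for
quick-cooking black jasmine rice: physical properties 30 (rehydration 15,
hardness 10, springiness 5), bioactive compounds 40 (TPC 10, TFC 10,
TAC 20) and sensory attributes 30 (flavor, softener, overall acceptance
10 each). Hardness is the single cost criterion — a firmer product is
worse — and is scored with the reversed transform.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import yaml

from .core import WEIGHT_SUM_TOL, CriterionSpec, GradeSet
from .errors import ConfigError


def default_criteria() -> list[CriterionSpec]:
    """The shipped nine-criterion configuration (weights sum to 100)."""
    return [
        CriterionSpec("rehydration", "physical", 15.0, "benefit", 3),
        CriterionSpec("hardness", "physical", 10.0, "cost", 3),
        CriterionSpec("springiness", "physical", 5.0, "benefit", 3),
        CriterionSpec("tpc", "bioactive", 10.0, "benefit", 3),
        CriterionSpec("tfc", "bioactive", 10.0, "benefit", 3),
        CriterionSpec("tac", "bioactive", 20.0, "benefit", 3),
        CriterionSpec("flavor", "sensory", 10.0, "benefit", 30),
        CriterionSpec("softener", "sensory", 10.0, "benefit", 30),
        CriterionSpec("overall_acceptance", "sensory", 10.0, "benefit", 30),
    ]


def criteria_to_dicts(criteria: Sequence[CriterionSpec]) -> list[dict]:
    return [
        {
            "id": c.id,
            "group": c.group,
            "weight": c.weight,
            "direction": c.direction,
            "expected_n": c.expected_n,
        }
        for c in criteria
    ]


def _parse_criteria(items) -> list[CriterionSpec]:
    if not isinstance(items, list) or not items:
        raise ConfigError("criteria config must be a non-empty list of criterion mappings")
    out = []
    for i, item in enumerate(items):
        try:
            out.append(
                CriterionSpec(
                    id=str(item["id"]),
                    group=str(item["group"]),
                    weight=float(item["weight"]),
                    direction=str(item.get("direction", "benefit")),
                    expected_n=int(item.get("expected_n", 3)),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"criterion #{i}: missing field {exc}") from exc
    return out


def _parse_grade_set(mapping) -> GradeSet:
    apexes = tuple(float(x) for x in mapping["apexes"])
    reps = mapping.get("representative_values")
    labels = mapping.get("labels")
    kwargs: dict = {"apexes": apexes}
    if labels is not None:
        kwargs["labels"] = tuple(str(x) for x in labels)
    elif len(apexes) != 6:
        kwargs["labels"] = tuple(f"G{i + 1}" for i in range(len(apexes)))
    if reps is not None:
        kwargs["representative_values"] = tuple(float(x) for x in reps)
    return GradeSet(**kwargs)


def load_config(path: str | Path) -> tuple[list[CriterionSpec], GradeSet]:
    """Load a criteria configuration from a YAML or JSON file.

    The file holds either a bare list of criterion mappings, or a mapping
    with keys ``criteria`` and optionally ``grade_set`` (``{apexes: [...],
    representative_values: [...]}``). A weight total other than 100 is
    reported as a warning, not an error: the overall index is invariant
    under a positive rescaling of all weights, so any consistent
    weighting ranks identically.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if isinstance(data, list):
        criteria, grade_set = _parse_criteria(data), GradeSet()
    elif isinstance(data, dict):
        criteria = _parse_criteria(data.get("criteria"))
        grade_set = _parse_grade_set(data["grade_set"]) if "grade_set" in data else GradeSet()
    else:
        raise ConfigError(f"unrecognised config structure in {path}")
    ids = [c.id for c in criteria]
    if len(set(ids)) != len(ids):
        raise ConfigError(f"duplicate criterion ids in {path}: {sorted(ids)}")
    total = sum(c.weight for c in criteria)
    if total <= 0:
        raise ConfigError(f"criterion weights in {path} must have a positive total, got {total}")
    if abs(total - 100.0) > WEIGHT_SUM_TOL:
        warnings.warn(
            f"criterion weights in {path} sum to {total}, not 100; the ranking is "
            "unaffected (indices are invariant under weight rescaling)",
            stacklevel=2,
        )
    return criteria, grade_set


def save_config(criteria: Sequence[CriterionSpec], path: str | Path,
                grade_set: GradeSet | None = None) -> None:
    """Write a criteria configuration as YAML."""
    payload: dict = {"criteria": criteria_to_dicts(criteria)}
    if grade_set is not None:
        payload["grade_set"] = {
            "labels": [str(x) for x in grade_set.labels],
            "apexes": [float(x) for x in grade_set.apexes],
            "representative_values": [float(x) for x in grade_set.reps],
        }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
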