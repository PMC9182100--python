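"""Shared fixtures and an independent brute-force oracle.

The oracle re-implements the scoring pipeline as a naive per-datum pure-
Python loop with its own triangular-membership formula, deliberately
sharing no code with the package, so pipeline results can be checked
against it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from famrank import CriterionSpec, default_criteria


@pytest.fixture
def criteria() -> list[CriterionSpec]:
    return default_criteria()


@pytest.fixture
def small_dataset() -> pd.DataFrame:
    """Deterministic 3-condition dataset over the default nine criteria."""
    rng = np.random.default_rng(1234)
    rows = []
    for cond in ("c1", "c2", "c3"):
        for crit in default_criteria():
            n = 4 if crit.group == "sensory" else 2
            for rep in range(1, n + 1):
                value = (
                    float(rng.integers(1, 10))
                    if crit.group == "sensory"
                    else float(np.round(rng.normal(50, 10), 3))
                )
                rows.append((cond, crit.id, rep, value))
    return pd.DataFrame(rows, columns=["condition_id", "criterion_id", "replicate_id", "value"])


def random_instance(rng: np.random.Generator, n_conditions: int) -> pd.DataFrame:
    """A random complete instance over the default criteria."""
    rows = []
    for i in range(n_conditions):
        cond = f"cond{i:02d}"
        for crit in default_criteria():
            n = int(rng.integers(1, 6))
            for rep in range(1, n + 1):
                value = (
                    float(rng.integers(1, 10))
                    if crit.group == "sensory"
                    else float(rng.normal(0, 100))
                )
                rows.append((cond, crit.id, rep, value))
    return pd.DataFrame(rows, columns=["condition_id", "criterion_id", "replicate_id", "value"])


# ---------------------------------------------------------------------------
# Brute-force oracle (no famrank imports beyond CriterionSpec metadata)
# ---------------------------------------------------------------------------

_APEXES = [10.0, 8.0, 6.0, 4.0, 2.0, 0.0]


def _oracle_memberships(score: float) -> list[float]:
    """Triangular memberships from first principles: each grade is a
    triangle with apex at its value and feet at the neighbouring apexes."""
    out = []
    for g, apex in enumerate(_APEXES):
        left = _APEXES[g - 1] if g > 0 else float("inf")  # neighbour above
        right = _APEXES[g + 1] if g < len(_APEXES) - 1 else float("-inf")
        if score == apex:
            mu = 1.0
        elif right < score < apex:
            mu = (score - right) / (apex - right)
        elif apex < score < left:
            mu = (left - score) / (left - apex)
        else:
            mu = 0.0
        # outermost grades extend flat beyond their apex
        if g == 0 and score > apex:
            mu = 1.0
        if g == len(_APEXES) - 1 and score < apex:
            mu = 1.0
        out.append(mu)
    return out


def oracle_overall_indices(frame: pd.DataFrame, criteria) -> dict[str, float]:
    """Naive loop: scale -> memberships -> weight -> accumulate -> centroid."""
    by_id = {c.id: c for c in criteria}
    pooled: dict[str, list[float]] = {}
    for row in frame.itertuples():
        pooled.setdefault(row.criterion_id, []).append(float(row.value))
    bounds = {cid: (min(vs), max(vs)) for cid, vs in pooled.items()}

    counts: dict[tuple[str, str], int] = {}
    for row in frame.itertuples():
        key = (row.condition_id, row.criterion_id)
        counts[key] = counts.get(key, 0) + 1

    masses: dict[str, list[float]] = {}
    weights: dict[str, float] = {}
    for row in frame.itertuples():
        crit = by_id[row.criterion_id]
        a, b = bounds[row.criterion_id]
        if b == a:
            score = 5.0
        elif crit.direction == "cost":
            score = 10.0 * (b - float(row.value)) / (b - a)
        else:
            score = 10.0 * (float(row.value) - a) / (b - a)
        share = crit.weight / counts[(row.condition_id, row.criterion_id)]
        mu = _oracle_memberships(score)
        acc = masses.setdefault(row.condition_id, [0.0] * len(_APEXES))
        for g in range(len(_APEXES)):
            acc[g] += share * mu[g]
        weights[row.condition_id] = weights.get(row.condition_id, 0.0) + share

    return {
        cond: sum(m * v for m, v in zip(acc, _APEXES)) / weights[cond]
        for cond, acc in masses.items()
    }
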