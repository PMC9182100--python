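"""Fuzzy analytical method (FAM) core.

The FAM turns heterogeneous measurements — instrumental replicates and
sensory panel scores in incompatible units — into a single 0–10 overall
performance index per processing condition:

1. every raw datum is min–max mapped onto a common fuzzy scale [0, 10]
   using bounds pooled over *all* conditions (direction-aware: for a cost
   criterion such as hardness the mapping is reversed, so 10 always means
   "best");
2. each fuzzy score is fuzzified into six triangular performance grades
   A (best) … F (worst) forming a Ruspini partition (memberships sum to 1);
3. each datum's grade-membership vector is scaled by its weight share —
   a criterion's weight divided by its datum count, so unequal replication
   (3 instrumental replicates vs 30 panelists) carries equal criterion
   weight;
4. the weighted vectors are summed per condition into an index score
   I = [IA, …, IF]ᵀ and defuzzified as the centroid of the grade
   representative values, yielding the overall performance index.

Conditions are ranked by descending overall index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, MissingDataError, OutOfBoundsError

logger = logging.getLogger(__name__)

#: Absolute tolerance for floating-point equality checks throughout.
FLOAT_TOL = 1e-9

#: Tolerance for validating that criterion weights sum to 100.
WEIGHT_SUM_TOL = 1e-6

RECORD_COLUMNS = ("condition_id", "criterion_id", "replicate_id", "value")

Direction = Literal["benefit", "cost"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CriterionSpec:
    """One scored sub-criterion.

    Parameters
    ----------
    id:
        Short label, e.g. ``"rehydration"`` or ``"hardness"``.
    group:
        One of ``"physical"``, ``"bioactive"``, ``"sensory"``. Sensory
        criteria are additionally range-checked to the 1–9 hedonic scale.
    weight:
        Weight in percent points; the default nine criteria sum to 100.
    direction:
        ``"benefit"`` (larger raw values are better) or ``"cost"``
        (smaller is better; scored with the reversed transform).
    expected_n:
        Data points expected per condition (replicates or panelists).
        A mismatch is a warning, not an error: the method tolerates
        unequal data by weight apportionment.
    """

    id: str
    group: str
    weight: float
    direction: Direction = "benefit"
    expected_n: int = 3

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ConfigError(f"criterion {self.id!r}: weight must be >= 0, got {self.weight}")
        if self.direction not in ("benefit", "cost"):
            raise ConfigError(
                f"criterion {self.id!r}: direction must be 'benefit' or 'cost', got {self.direction!r}"
            )
        if self.group not in ("physical", "bioactive", "sensory"):
            raise ConfigError(
                f"criterion {self.id!r}: group must be physical/bioactive/sensory, got {self.group!r}"
            )
        if self.expected_n < 1:
            raise ConfigError(f"criterion {self.id!r}: expected_n must be >= 1")


@dataclass(frozen=True)
class MeasurementRecord:
    """One raw datum: a (condition, criterion, replicate, value) tuple."""

    condition_id: str
    criterion_id: str
    replicate_id: int
    value: float


@dataclass(frozen=True)
class ScaleBounds:
    """Pooled min/max of one criterion's raw values across all conditions."""

    criterion_id: str
    a: float  # pooled minimum
    b: float  # pooled maximum

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise DataError(f"bounds for {self.criterion_id!r} are not finite: [{self.a}, {self.b}]")
        if self.a > self.b:
            raise DataError(f"bounds for {self.criterion_id!r} inverted: a={self.a} > b={self.b}")

    @property
    def degenerate(self) -> bool:
        return self.b - self.a <= 0.0


@dataclass(frozen=True)
class GradeSet:
    """Ordered triangular fuzzy performance grades A (best) … F (worst).

    Each grade is a triangular membership function on the fuzzy scale
    [0, 10] whose apex sits at its own characteristic value and whose feet
    sit at the apexes of the neighbouring grades, so that at every point
    of the scale the memberships sum to exactly 1 (a Ruspini partition).
    The default partition places apexes at 10, 8, 6, 4, 2, 0.

    ``representative_values`` (defaulting to the apexes) are the grade
    values used by centroid defuzzification.
    """

    labels: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")
    apexes: tuple[float, ...] = (10.0, 8.0, 6.0, 4.0, 2.0, 0.0)
    representative_values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.apexes):
            raise ConfigError("grade set: labels and apexes must have equal length")
        if len(self.apexes) < 2:
            raise ConfigError("grade set: at least two grades required")
        diffs = np.diff(self.apexes)
        if not np.all(diffs < 0):
            raise ConfigError("grade set: apexes must strictly decrease from best to worst")
        if min(self.apexes) < 0 or max(self.apexes) > 10:
            raise ConfigError("grade set: apexes must lie in [0, 10]")
        if self.representative_values is not None and len(self.representative_values) != len(
            self.apexes
        ):
            raise ConfigError("grade set: representative_values must match apexes in length")

    @property
    def n_grades(self) -> int:
        return len(self.apexes)

    @property
    def reps(self) -> np.ndarray:
        if self.representative_values is not None:
            return np.asarray(self.representative_values, dtype=float)
        return np.asarray(self.apexes, dtype=float)

    def memberships(self, scores) -> np.ndarray:
        """Grade membership matrix for fuzzy ``scores``.

        Returns shape ``(n_scores, n_grades)`` for array input, or a
        1-D vector of length ``n_grades`` for a scalar. Memberships are
        non-negative and sum to 1 at every score (Ruspini property);
        outside the outermost apexes the nearest grade holds full
        membership.
        """
        scalar = np.isscalar(scores)
        x = np.atleast_1d(np.asarray(scores, dtype=float))
        if np.any(x < -FLOAT_TOL) or np.any(x > 10 + FLOAT_TOL):
            bad = x[(x < -FLOAT_TOL) | (x > 10 + FLOAT_TOL)]
            raise OutOfBoundsError(f"fuzzy scores outside [0, 10]: {bad[:5]}")
        x = np.clip(x, 0.0, 10.0)
        knots = np.asarray(self.apexes[::-1], dtype=float)  # ascending for interp
        out = np.empty((x.size, self.n_grades), dtype=float)
        for g in range(self.n_grades):
            hat = np.zeros(self.n_grades)
            hat[self.n_grades - 1 - g] = 1.0  # indicator in ascending-knot order
            out[:, g] = np.interp(x, knots, hat)
        return out[0] if scalar else out


@dataclass
class IndexScore:
    """Weight-scaled grade-mass vector I = [IA, …, IF]ᵀ.

    ``masses`` are non-negative and sum to ``total_weight``: each datum
    contributes its weight share split across grades according to its
    memberships, and aggregation simply adds vectors.
    """

    masses: np.ndarray
    total_weight: float

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses < -FLOAT_TOL):
            raise ConfigError(f"index score has negative grade mass: {self.masses}")
        if abs(float(self.masses.sum()) - self.total_weight) > 1e-6 * max(1.0, self.total_weight):
            raise ConfigError(
                f"index score masses sum to {self.masses.sum()}, expected {self.total_weight}"
            )


@dataclass
class RankingResult:
    """Per-condition overall performance indices with competition ranks.

    Attributes
    ----------
    table:
        DataFrame with columns ``condition_id, overall_index, rank,
        tie_flag``, sorted by descending index (ties broken by
        condition_id for deterministic output order).
    grade_masses:
        DataFrame indexed by condition with one column per grade label
        plus ``total_weight`` — the aggregated index score I per
        condition, for auditability.
    bounds:
        The pooled ScaleBounds used, keyed by criterion id.
    """

    table: pd.DataFrame
    grade_masses: pd.DataFrame
    bounds: dict[str, ScaleBounds] = field(default_factory=dict)

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["condition_id"])

    def index_of(self, condition_id: str) -> float:
        row = self.table.loc[self.table["condition_id"] == condition_id, "overall_index"]
        if row.empty:
            raise KeyError(condition_id)
        return float(row.iloc[0])


# ---------------------------------------------------------------------------
# Record container helpers
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[MeasurementRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalise measurement records to the canonical long-format frame."""
    if isinstance(records, pd.DataFrame):
        missing = set(RECORD_COLUMNS) - set(records.columns)
        if missing:
            raise DataError(f"records frame missing columns: {sorted(missing)}")
        frame = records.loc[:, list(RECORD_COLUMNS)].copy()
    else:
        frame = pd.DataFrame(
            [(r.condition_id, r.criterion_id, r.replicate_id, r.value) for r in records],
            columns=list(RECORD_COLUMNS),
        )
    if frame.empty:
        raise DataError("no measurement records provided")
    frame["value"] = frame["value"].astype(float)
    if not np.isfinite(frame["value"]).all():
        bad = frame.loc[~np.isfinite(frame["value"])]
        raise DataError(f"non-finite measurement values at rows {bad.index.tolist()[:5]}")
    return frame


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_bounds(records, criterion_id: str) -> ScaleBounds:
    """Pooled scale bounds for one criterion.

    The minimum ``a`` and maximum ``b`` are taken over the criterion's
    values across *all* conditions and replicates, so fuzzy scores are
    comparable between conditions.
    """
    frame = records_to_frame(records)
    values = frame.loc[frame["criterion_id"] == criterion_id, "value"]
    if values.empty:
        raise MissingDataError(f"no measurements for criterion {criterion_id!r}")
    return ScaleBounds(criterion_id, float(values.min()), float(values.max()))


def fuzzy_scale(value, bounds: ScaleBounds, direction: Direction = "benefit"):
    """Map a raw value onto the fuzzy scale [0, 10].

    Benefit criteria use the forward transform ``10 * (v - a) / (b - a)``
    (pooled best → 10); cost criteria the reverse, ``10 * (b - v) / (b - a)``
    (pooled *smallest* → 10). A degenerate criterion (a == b) is
    uninformative: every value maps to the neutral score 5.0, with a
    warning.

    Accepts scalars or arrays.
    """
    if direction not in ("benefit", "cost"):
        raise ConfigError(f"direction must be 'benefit' or 'cost', got {direction!r}")
    scalar = np.isscalar(value)
    v = np.atleast_1d(np.asarray(value, dtype=float))
    if np.any(v < bounds.a - FLOAT_TOL) or np.any(v > bounds.b + FLOAT_TOL):
        raise OutOfBoundsError(
            f"value(s) outside bounds [{bounds.a}, {bounds.b}] for {bounds.criterion_id!r}; "
            "bounds must be pooled from the same record set"
        )
    if bounds.degenerate:
        warnings.warn(
            f"criterion {bounds.criterion_id!r} is constant (a == b == {bounds.a}); "
            "assigning neutral fuzzy score 5.0",
            stacklevel=2,
        )
        out = np.full_like(v, 5.0)
    else:
        span = bounds.b - bounds.a
        if direction == "benefit":
            out = 10.0 * (v - bounds.a) / span
            hi, lo = bounds.b, bounds.a
        else:
            out = 10.0 * (bounds.b - v) / span
            hi, lo = bounds.a, bounds.b
        # snap exact endpoint values so pooled best/worst score exactly 10/0
        out = np.where(v == hi, 10.0, np.where(v == lo, 0.0, np.clip(out, 0.0, 10.0)))
    return float(out[0]) if scalar else out


def grade_memberships(score, grade_set: GradeSet | None = None) -> np.ndarray:
    """Triangular grade memberships of a fuzzy score (sum to 1)."""
    gs = grade_set or GradeSet()
    return gs.memberships(score)


def per_datum_weight(criterion: CriterionSpec, n_data: int) -> float:
    """Weight share carried by each datum of a criterion.

    A criterion's data jointly carry exactly its stated weight regardless
    of replication: 30 panelist scores at weight 10 each carry 1/3, three
    instrumental replicates at weight 20 each carry 20/3.
    """
    if n_data < 1:
        raise DataError(f"criterion {criterion.id!r} has no data (n_data={n_data})")
    return criterion.weight / n_data


def index_score(memberships, weight_share: float) -> IndexScore:
    """Scale a membership vector by its weight share into an index score."""
    if weight_share < 0:
        raise ConfigError(f"weight share must be >= 0, got {weight_share}")
    m = np.asarray(memberships, dtype=float)
    if abs(m.sum() - 1.0) > 1e-6:
        raise DataError(f"memberships must sum to 1, got {m.sum()}")
    return IndexScore(masses=weight_share * m, total_weight=float(weight_share))


def aggregate(index_scores: Sequence[IndexScore]) -> IndexScore:
    """Componentwise sum of index scores.

    For a complete condition under the default configuration this combines
    all 108 per-datum scores into one vector with total weight 100.
    """
    scores = list(index_scores)
    if not scores:
        raise DataError("cannot aggregate an empty collection of index scores")
    n = scores[0].masses.size
    if any(s.masses.size != n for s in scores):
        raise ConfigError("index scores built on different grade sets cannot be combined")
    masses = np.sum([s.masses for s in scores], axis=0)
    total = float(sum(s.total_weight for s in scores))
    return IndexScore(masses=masses, total_weight=total)


def defuzzify(index: IndexScore, grade_set: GradeSet | None = None) -> float:
    """Overall performance index: weighted centroid of grade values.

    ``sum(masses * representative_values) / total_weight`` — on the same
    0–10 scale as the fuzzy scores.
    """
    gs = grade_set or GradeSet()
    if index.total_weight <= 0:
        raise DataError("cannot defuzzify an index score with zero total weight")
    if index.masses.size != gs.n_grades:
        raise ConfigError("index score and grade set disagree on the number of grades")
    # normalise before the dot product so a single-grade index hits the
    # grade value exactly (no (w * v) / w rounding)
    return float(np.dot(index.masses / index.total_weight, gs.reps))


def validate_criteria(criteria: Sequence[CriterionSpec]) -> None:
    """Check a criteria configuration: unique ids, weights summing to 100."""
    ids = [c.id for c in criteria]
    if len(set(ids)) != len(ids):
        raise ConfigError(f"duplicate criterion ids: {sorted(ids)}")
    total = sum(c.weight for c in criteria)
    if abs(total - 100.0) > WEIGHT_SUM_TOL:
        raise ConfigError(f"criterion weights must sum to 100, got {total}")


def rank_conditions(
    records,
    criteria: Sequence[CriterionSpec],
    grade_set: GradeSet | None = None,
    *,
    check_weights: bool = True,
) -> RankingResult:
    """Run the full FAM pipeline and rank conditions.

    For every condition: pool bounds per criterion, fuzzy-scale each
    datum, fuzzify into grades, weight by ``criterion.weight / n_data``,
    aggregate into the condition's index score, and defuzzify. Conditions
    are sorted by descending overall index; exact ties share the better
    (competition) rank, carry ``tie_flag=True``, and fall back to
    condition_id order.

    ``check_weights=False`` skips the sum-to-100 validation (the overall
    index is invariant to a positive rescaling of all weights, so any
    consistent weighting is usable).
    """
    gs = grade_set or GradeSet()
    criteria = list(criteria)
    if check_weights:
        validate_criteria(criteria)
    frame = records_to_frame(records)
    crit_ids = [c.id for c in criteria]
    by_crit = {c.id: c for c in criteria}

    extra = set(frame["criterion_id"].unique()) - set(crit_ids)
    if extra:
        raise ConfigError(f"records contain criteria absent from the configuration: {sorted(extra)}")

    # completeness: every condition needs >= 1 datum for every criterion
    conditions = sorted(frame["condition_id"].unique())
    counts = frame.groupby(["condition_id", "criterion_id"]).size()
    gaps = [
        (cond, cid)
        for cond in conditions
        for cid in crit_ids
        if (cond, cid) not in counts.index
    ]
    if gaps:
        raise MissingDataError(f"missing (condition, criterion) cells: {gaps}")

    bounds = {cid: compute_bounds(frame, cid) for cid in crit_ids}
    for cid, bd in bounds.items():
        logger.info("bounds %-20s a=%g b=%g", cid, bd.a, bd.b)

    # vectorised per-datum pipeline
    crit = frame["criterion_id"].to_numpy()
    a = np.array([bounds[c].a for c in crit])
    b = np.array([bounds[c].b for c in crit])
    is_cost = np.array([by_crit[c].direction == "cost" for c in crit])
    v = frame["value"].to_numpy()
    span = b - a
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(is_cost, 10.0 * (b - v), 10.0 * (v - a)) / span
    # snap exact endpoint values so pooled best/worst score exactly 10/0
    hi = np.where(is_cost, v == a, v == b)
    lo = np.where(is_cost, v == b, v == a)
    score = np.where(hi, 10.0, np.where(lo, 0.0, score))
    degenerate = span <= 0
    if degenerate.any():
        for cid in sorted(set(crit[degenerate])):
            warnings.warn(
                f"criterion {cid!r} is constant across all conditions; "
                "assigning neutral fuzzy score 5.0",
                stacklevel=2,
            )
        score = np.where(degenerate, 5.0, score)
    score = np.clip(score, 0.0, 10.0)

    n_per_cell = counts.loc[list(zip(frame["condition_id"], crit))].to_numpy()
    share = np.array([by_crit[c].weight for c in crit]) / n_per_cell

    member = gs.memberships(score)  # (n_records, n_grades)
    masses = member * share[:, None]

    mass_frame = pd.DataFrame(masses, columns=list(gs.labels))
    mass_frame["condition_id"] = frame["condition_id"].to_numpy()
    agg = mass_frame.groupby("condition_id").sum()
    agg["total_weight"] = agg[list(gs.labels)].sum(axis=1)
    normalised = agg[list(gs.labels)].to_numpy() / agg["total_weight"].to_numpy()[:, None]
    overall = normalised @ gs.reps

    table = pd.DataFrame(
        {"condition_id": agg.index.to_numpy(), "overall_index": overall}
    ).sort_values(["overall_index", "condition_id"], ascending=[False, True], kind="stable")

    # competition ranking on indices equal to within FLOAT_TOL
    rounded = np.round(table["overall_index"].to_numpy(), 9)
    ranks = np.empty(len(rounded), dtype=int)
    tie = np.zeros(len(rounded), dtype=bool)
    pos = 0
    while pos < len(rounded):
        end = pos
        while end + 1 < len(rounded) and rounded[end + 1] == rounded[pos]:
            end += 1
        ranks[pos : end + 1] = pos + 1
        tie[pos : end + 1] = end > pos
        pos = end + 1
    table["rank"] = ranks
    table["tie_flag"] = tie
    table = table.reset_index(drop=True)

    return RankingResult(table=table, grade_masses=agg, bounds=bounds)
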