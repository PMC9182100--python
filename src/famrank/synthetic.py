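"""Synthetic factorial datasets with the structure the ranking method assumes.

The study design is a 3 x 3 x 3 full factorial in completely randomised
order: baking-powder concentration (0.1, 0.3, 0.5 %) x soaking temperature
(room ~25, 50, 60 degC) x soaking time (10, 20, 30 min), 27 conditions in
all. Each condition yields 3 instrumental replicates for each of the six
physical/bioactive criteria and 30 panelist scores (integers 1-9) for each
of the three sensory attributes: 108 data per condition.

No measured dataset is distributed with the original study, so this module
generates one. The shipped :func:`default_effect_model` encodes the
*directions* of the reported factor effects — e.g. higher soaking
temperature and longer soaking time depress rehydration capacity; higher
baking-powder concentration depresses all three bioactive contents but
raises the sensory scores; springiness peaks at the middle baking-powder
level — with synthetic magnitudes chosen so the planted best condition
(0.1 % baking powder, room temperature, 30 min) separates from its nearest
competitor by at least two standard deviations of the overall-index noise.
The magnitudes are NOT estimates of the real effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CriterionSpec, GradeSet, RankingResult, rank_conditions
from .config import default_criteria
from .errors import ConfigError

SENSORY_MIN, SENSORY_MAX = 1, 9


@dataclass(frozen=True)
class DesignSpec:
    """The factorial design: factor levels and replication counts."""

    baking_powder_levels: tuple[float, ...] = (0.1, 0.3, 0.5)
    temperature_levels: tuple[float, ...] = (25.0, 50.0, 60.0)
    time_levels: tuple[float, ...] = (10.0, 20.0, 30.0)
    n_instrumental_reps: int = 3
    n_panelists: int = 30

    def __post_init__(self) -> None:
        for name, levels in (
            ("baking_powder_levels", self.baking_powder_levels),
            ("temperature_levels", self.temperature_levels),
            ("time_levels", self.time_levels),
        ):
            if not levels:
                raise ConfigError(f"{name} must be non-empty")
            if len(set(levels)) != len(levels):
                raise ConfigError(f"duplicate levels in {name}: {levels}")
        if self.n_instrumental_reps < 1 or self.n_panelists < 1:
            raise ConfigError("replication counts must be >= 1")

    @property
    def n_conditions(self) -> int:
        return (
            len(self.baking_powder_levels)
            * len(self.temperature_levels)
            * len(self.time_levels)
        )


@dataclass(frozen=True)
class Condition:
    """One cell of the factorial design."""

    condition_id: str
    baking_powder: float
    temperature: float
    time: float


def _fmt(x: float) -> str:
    return f"{x:g}"


def condition_id_for(bp: float, temp: float, time: float) -> str:
    return f"BP{_fmt(bp)}_T{_fmt(temp)}_M{_fmt(time)}"


def enumerate_design(spec: DesignSpec | None = None) -> list[Condition]:
    """All factor-level combinations with stable human-readable ids.

    The id encodes the levels, e.g. ``BP0.1_T25_M30`` for 0.1 % baking
    powder, 25 degC, 30 min. Order is the nested Cartesian product
    (baking powder outermost, time innermost).
    """
    spec = spec or DesignSpec()
    return [
        Condition(condition_id_for(bp, t, m), bp, t, m)
        for bp in spec.baking_powder_levels
        for t in spec.temperature_levels
        for m in spec.time_levels
    ]


@dataclass(frozen=True)
class CriterionEffect:
    """Additive effect model for one criterion on coded factor levels.

    Factor levels are coded by rank as -1 / 0 / +1 (low / mid / high); only
    the ordering of levels matters downstream, not their physical spacing.
    The mean response of a condition is::

        baseline + bp_slope*bp + temp_slope*temp + time_slope*time
                 + bp_peak * (1 - bp**2)

    where the quadratic ``bp_peak`` term lets a response peak at the middle
    baking-powder level (used for springiness). Gaussian noise with
    ``noise_sd`` is added per datum; for ``sensory=True`` criteria the
    noisy latent value is rounded to the nearest integer and clipped to
    the 1-9 hedonic scale.
    """

    baseline: float
    bp_slope: float = 0.0
    temp_slope: float = 0.0
    time_slope: float = 0.0
    bp_peak: float = 0.0
    noise_sd: float = 0.0
    sensory: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def mean(self, bp: float, temp: float, time: float) -> float:
        """Noiseless mean at coded factor levels."""
        return (
            self.baseline
            + self.bp_slope * bp
            + self.temp_slope * temp
            + self.time_slope * time
            + self.bp_peak * (1.0 - bp * bp)
        )


#: Effect model per criterion. Mapping criterion_id -> CriterionEffect.
EffectModel = Mapping[str, CriterionEffect]


def default_effect_model() -> dict[str, CriterionEffect]:
    """The shipped effect model (directions from the study, magnitudes synthetic).

    Signs: rehydration rises with baking powder but falls with temperature
    and (weakly) time; hardness falls with baking powder and time but rises
    with temperature; springiness peaks at the middle baking-powder level;
    all three bioactive contents fall with every factor, dominated by the
    baking-powder effect; sensory scores rise with baking powder and
    soaking time, softener falling slightly with temperature. Units:
    rehydration %, hardness N, springiness dimensionless ratio, TPC
    mg GAE/100 g, TFC mg QAE/100 g, TAC mg/10 mL, sensory 1-9 hedonic.
    """
    return {
        "rehydration": CriterionEffect(250.0, bp_slope=3.0, temp_slope=-20.0,
                                       time_slope=-4.0, noise_sd=3.0),
        "hardness": CriterionEffect(30.0, bp_slope=-1.0, temp_slope=4.5,
                                    time_slope=-1.2, noise_sd=0.5),
        "springiness": CriterionEffect(0.80, bp_peak=0.06, noise_sd=0.008),
        "tpc": CriterionEffect(120.0, bp_slope=-11.0, temp_slope=-1.5,
                               time_slope=-0.8, noise_sd=1.5),
        "tfc": CriterionEffect(60.0, bp_slope=-5.5, temp_slope=-0.8,
                               time_slope=-0.4, noise_sd=0.8),
        "tac": CriterionEffect(5.0, bp_slope=-1.3, temp_slope=-0.15,
                               time_slope=-0.08, noise_sd=0.08),
        "flavor": CriterionEffect(5.5, bp_slope=0.7, time_slope=0.8,
                                  noise_sd=0.6, sensory=True),
        "softener": CriterionEffect(5.5, bp_slope=0.7, temp_slope=-0.5,
                                    time_slope=1.0, noise_sd=0.6, sensory=True),
        "overall_acceptance": CriterionEffect(5.5, bp_slope=0.5, time_slope=1.1,
                                              noise_sd=0.6, sensory=True),
    }


#: The condition the shipped defaults are constructed to favour.
PLANTED_BEST = condition_id_for(0.1, 25, 30)


def _coded(levels: Sequence[float]) -> dict[float, float]:
    """Rank-code sorted levels onto a symmetric grid in [-1, 1]."""
    srt = sorted(levels)
    if len(srt) == 1:
        return {srt[0]: 0.0}
    return {v: -1.0 + 2.0 * i / (len(srt) - 1) for i, v in enumerate(srt)}


def ground_truth_means(spec: DesignSpec | None = None,
                       model: EffectModel | None = None) -> pd.DataFrame:
    """Noiseless criterion means per condition (conditions x criteria)."""
    spec = spec or DesignSpec()
    model = model or default_effect_model()
    bp_code = _coded(spec.baking_powder_levels)
    t_code = _coded(spec.temperature_levels)
    m_code = _coded(spec.time_levels)
    rows = {}
    for cond in enumerate_design(spec):
        rows[cond.condition_id] = {
            cid: eff.mean(bp_code[cond.baking_powder], t_code[cond.temperature],
                          m_code[cond.time])
            for cid, eff in model.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless means and the implied best condition."""

    means: pd.DataFrame
    best_condition: str
    ranking: RankingResult = field(repr=False, default=None)


def simulate(spec: DesignSpec | None = None, model: EffectModel | None = None,
             seed: int = 0) -> pd.DataFrame:
    """Draw a full synthetic dataset: one row per (condition, criterion, replicate).

    Instrumental criteria get ``n_instrumental_reps`` Gaussian draws around
    the effect-model mean; sensory criteria get ``n_panelists`` latent
    Gaussian draws rounded to integers and clipped to [1, 9]. A single
    seeded generator drives the whole call, so output is byte-reproducible
    from (spec, model, seed). Defaults yield 27 x 108 = 2916 records.
    """
    spec = spec or DesignSpec()
    model = model or default_effect_model()
    rng = np.random.default_rng(seed)
    means = ground_truth_means(spec, model)
    chunks = []
    for cond in enumerate_design(spec):
        for cid, eff in model.items():
            n = spec.n_panelists if eff.sensory else spec.n_instrumental_reps
            mu = means.at[cond.condition_id, cid]
            draws = mu + rng.normal(0.0, 1.0, size=n) * eff.noise_sd
            if eff.sensory:
                draws = np.clip(np.rint(draws), SENSORY_MIN, SENSORY_MAX)
            chunks.append(
                pd.DataFrame(
                    {
                        "condition_id": cond.condition_id,
                        "criterion_id": cid,
                        "replicate_id": np.arange(1, n + 1),
                        "value": draws,
                    }
                )
            )
    return pd.concat(chunks, ignore_index=True)


def ground_truth_ranking(
    spec: DesignSpec | None = None,
    model: EffectModel | None = None,
    criteria: Sequence[CriterionSpec] | None = None,
    grade_set: GradeSet | None = None,
) -> GroundTruth:
    """Rank the noiseless condition means with the full scoring pipeline.

    Each condition contributes a single datum per criterion (its noiseless
    mean), so the criterion weights apply undivided. This defines the
    planted "best" condition against which recovery from noisy draws is
    judged.
    """
    spec = spec or DesignSpec()
    model = model or default_effect_model()
    criteria = list(criteria) if criteria is not None else default_criteria()
    means = ground_truth_means(spec, model)
    long = means.reset_index(names="condition_id").melt(
        id_vars="condition_id", var_name="criterion_id", value_name="value"
    )
    long["replicate_id"] = 1
    ranking = rank_conditions(long, criteria, grade_set)
    return GroundTruth(means=means, best_condition=ranking.best, ranking=ranking)


def flip_model(model: EffectModel) -> dict[str, CriterionEffect]:
    """Sign-flip every slope (and peak) of an effect model."""
    return {
        cid: replace(
            eff,
            bp_slope=-eff.bp_slope,
            temp_slope=-eff.temp_slope,
            time_slope=-eff.time_slope,
            bp_peak=-eff.bp_peak,
        )
        for cid, eff in model.items()
    }
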