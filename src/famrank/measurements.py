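"""Assay calculators turning raw instrument readings into criterion values.

Covers the three spectrophotometric bioactive assays and the gravimetric
rehydration test used for quick-cooking black jasmine rice:

* rehydration capacity — percent mass gain of the dried product after a
  hot-water soak;
* total phenolic content (TPC, Folin–Ciocalteu) and total flavonoid
  content (TFC, aluminium-nitrate colorimetry) — read off linear
  absorbance standard curves by inversion;
* total anthocyanin content (TAC) — single-wavelength absorbance at
  535 nm with fixed dilution factors.

Texture values (hardness, springiness) and sensory scores arrive as
numbers and need no conversion; :func:`convert_raw_readings` passes them
through when building a measurement table for the ranking pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, DataError


@dataclass(frozen=True)
class RehydrationWeights:
    """Dry (w1) and rehydrated (w2) sample masses in grams."""

    w1: float
    w2: float


@dataclass(frozen=True)
class StandardCurve:
    """Linear standard curve ``absorbance = slope * concentration + intercept``.

    ``response`` and ``units`` are descriptive metadata only; no unit
    conversion is performed.
    """

    slope: float
    intercept: float
    response: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ConfigError("standard curve slope must be nonzero")

    def absorbance(self, concentration: float) -> float:
        """Forward evaluation of the curve."""
        return self.slope * concentration + self.intercept


#: Gallic-acid standard curve for total phenolic content.
TPC_CURVE = StandardCurve(
    slope=0.471,
    intercept=-0.0146,
    response="absorbance at 725 nm",
    units="mg GAE/100 g sample",
)

#: Quercetin standard curve for total flavonoid content. The assay reads
#: absorbance at 420 nm; the curve's published caption names 725 nm — the
#: wavelength strings are metadata only and do not affect the arithmetic.
TFC_CURVE = StandardCurve(
    slope=0.2408,
    intercept=0.1632,
    response="absorbance at 420 nm",
    units="mg QAE/100 g sample",
)


@dataclass(frozen=True)
class TacInputs:
    """Inputs to the total-anthocyanin formula.

    a535: absorbance at 535 nm; extract_volume: total extract volume (mL);
    sample_mass: sample mass (mg).
    """

    a535: float
    extract_volume: float
    sample_mass: float


def rehydration_capacity(w: RehydrationWeights | None = None, *, w1: float | None = None,
                         w2: float | None = None) -> float:
    """Rehydration capacity in percent: ``100 * (w2 - w1) / w1``.

    Accepts either a :class:`RehydrationWeights` or ``w1=...``/``w2=...``
    keywords.
    """
    if w is not None:
        w1, w2 = w.w1, w.w2
    if w1 is None or w2 is None:
        raise ConfigError("rehydration_capacity needs both w1 and w2")
    if w1 <= 0:
        raise DataError(f"dry-sample mass w1 must be positive, got {w1}")
    if w2 < 0:
        raise DataError(f"rehydrated-sample mass w2 must be non-negative, got {w2}")
    return 100.0 * (w2 - w1) / w1


def concentration_from_absorbance(absorbance: float, curve: StandardCurve) -> float:
    """Invert a linear standard curve: ``(absorbance - intercept) / slope``.

    An absorbance below the curve's blank yields a negative concentration;
    it is returned as-is with a warning rather than clipped, since the
    downstream min–max scaling tolerates it.
    """
    conc = (absorbance - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"absorbance {absorbance} below blank level; negative concentration {conc:.4g} "
            "returned unclipped",
            stacklevel=2,
        )
    return conc


def total_anthocyanin(t: TacInputs | None = None, *, a535: float | None = None,
                      extract_volume: float | None = None, sample_mass: float | None = None) -> float:
    """Total anthocyanin content (mg/10 mL basis).

    ``[(A535 * V * 100) / (0.2 * m)] / 98.2`` with V the total extract
    volume (mL) and m the sample mass (mg). The 0.2 mL aliquot and the
    x100 dilution are part of the assay protocol and deliberately kept
    inside the formula.
    """
    if t is not None:
        a535, extract_volume, sample_mass = t.a535, t.extract_volume, t.sample_mass
    if a535 is None or extract_volume is None or sample_mass is None:
        raise ConfigError("total_anthocyanin needs a535, extract_volume and sample_mass")
    if sample_mass <= 0:
        raise DataError(f"sample mass must be positive, got {sample_mass}")
    if a535 < 0 or extract_volume < 0:
        raise DataError("absorbance and extract volume must be non-negative")
    return ((a535 * extract_volume * 100.0) / (0.2 * sample_mass)) / 98.2


# ---------------------------------------------------------------------------
# Raw-readings CSV converter
# ---------------------------------------------------------------------------

RAW_COLUMNS = ("condition_id", "assay", "replicate_id", "reading", "aux1", "aux2")

#: Assays that pass their reading straight through as the criterion value.
_PASSTHROUGH = {"hardness", "springiness", "flavor", "softener", "overall_acceptance"}


def convert_raw_readings(raw: pd.DataFrame) -> pd.DataFrame:
    """Convert a raw-readings table into the long-format measurement table.

    Input columns: ``condition_id, assay, replicate_id, reading, aux1, aux2``.
    Per assay the columns mean:

    ================  =========================  ===========  ============
    assay             reading                    aux1         aux2
    ================  =========================  ===========  ============
    rehydration       rehydrated mass w2 (g)     dry mass w1  —
    tpc               absorbance (725 nm)        —            —
    tfc               absorbance (420 nm)        —            —
    tac               absorbance (535 nm)        extract mL   sample mg
    others            the criterion value        —            —
    ================  =========================  ===========  ============

    Returns a frame with columns ``condition_id, criterion_id,
    replicate_id, value`` ready for the ranking pipeline.
    """
    missing = set(RAW_COLUMNS[:4]) - set(raw.columns)
    if missing:
        raise DataError(f"raw readings missing columns: {sorted(missing)}")

    def one(row) -> float:
        assay = row["assay"]
        if assay == "rehydration":
            return rehydration_capacity(w1=float(row["aux1"]), w2=float(row["reading"]))
        if assay == "tpc":
            return concentration_from_absorbance(float(row["reading"]), TPC_CURVE)
        if assay == "tfc":
            return concentration_from_absorbance(float(row["reading"]), TFC_CURVE)
        if assay == "tac":
            return total_anthocyanin(
                a535=float(row["reading"]),
                extract_volume=float(row["aux1"]),
                sample_mass=float(row["aux2"]),
            )
        if assay in _PASSTHROUGH:
            return float(row["reading"])
        raise DataError(f"unknown assay {assay!r}")

    out = pd.DataFrame(
        {
            "condition_id": raw["condition_id"],
            "criterion_id": raw["assay"],
            "replicate_id": raw["replicate_id"],
            "value": raw.apply(one, axis=1),
        }
    )
    return out.reset_index(drop=True)
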