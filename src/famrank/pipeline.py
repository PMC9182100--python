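"""End-to-end pipeline: ingest CSV, validate, score, rank, report.

Input data is a long-format UTF-8 CSV with header
``condition_id,criterion_id,replicate_id,value`` ("." decimal separator).
Validation distinguishes fatal issues (missing condition x criterion
cells, values outside the hedonic scale for sensory criteria, non-finite
values) from warnings (a datum count differing from ``expected_n`` — the
method tolerates unequal data by weight apportionment). ``run`` writes a
ranking CSV, a per-condition grade-mass breakdown CSV and a markdown
report naming the top condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import default_criteria, load_config
from .core import (
    RECORD_COLUMNS,
    CriterionSpec,
    GradeSet,
    RankingResult,
    rank_conditions,
    records_to_frame,
)
from .errors import ConfigError, DataError, ValidationError

logger = logging.getLogger(__name__)


def read_records_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format measurement CSV into the canonical frame."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"data file not found: {path}")
    frame = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return records_to_frame(frame)


def write_records_csv(frame: pd.DataFrame, path: str | Path) -> None:
    records_to_frame(frame).to_csv(path, index=False)


@dataclass(frozen=True)
class Issue:
    """One validation finding."""

    severity: str  # "fatal" | "warning"
    condition_id: str | None
    criterion_id: str | None
    message: str


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def fatal(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "fatal"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.fatal

    def raise_if_fatal(self) -> None:
        if self.fatal:
            lines = "; ".join(i.message for i in self.fatal[:10])
            raise ValidationError(f"{len(self.fatal)} fatal validation issue(s): {lines}",
                                  issues=self.issues)


def validate(records, criteria: Sequence[CriterionSpec]) -> ValidationReport:
    """Check a measurement table against a criteria configuration.

    Fatal: a condition missing all data for some criterion; a sensory
    value outside the 1-9 hedonic scale (row-addressed); criteria in the
    data that the configuration does not define. Warning: a (condition,
    criterion) datum count different from ``expected_n`` — the pipeline
    proceeds, apportioning the criterion weight over the actual count.
    """
    frame = records_to_frame(records)
    criteria = list(criteria)
    by_id = {c.id: c for c in criteria}
    report = ValidationReport()

    extra = sorted(set(frame["criterion_id"].unique()) - set(by_id))
    for cid in extra:
        report.issues.append(
            Issue("fatal", None, cid, f"criterion {cid!r} in data but not in configuration")
        )

    counts = frame.groupby(["condition_id", "criterion_id"]).size()
    for cond in sorted(frame["condition_id"].unique()):
        for cid, spec in by_id.items():
            n = int(counts.get((cond, cid), 0))
            if n == 0:
                report.issues.append(
                    Issue("fatal", cond, cid, f"condition {cond!r} has no data for {cid!r}")
                )
            elif n != spec.expected_n:
                report.issues.append(
                    Issue(
                        "warning",
                        cond,
                        cid,
                        f"condition {cond!r}, criterion {cid!r}: {n} data points "
                        f"(expected {spec.expected_n}); weight apportioned over {n}",
                    )
                )

    sensory_ids = {c.id for c in criteria if c.group == "sensory"}
    if sensory_ids:
        mask = frame["criterion_id"].isin(sensory_ids) & (
            (frame["value"] < 1) | (frame["value"] > 9)
        )
        for row in frame.loc[mask].itertuples():
            report.issues.append(
                Issue(
                    "fatal",
                    row.condition_id,
                    row.criterion_id,
                    f"row {row.Index}: sensory value {row.value} outside the 1-9 "
                    f"hedonic scale ({row.condition_id!r}, {row.criterion_id!r}, "
                    f"replicate {row.replicate_id})",
                )
            )
    return report


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    data: str | Path
    criteria_config: str | Path | None = None  # None -> shipped defaults
    out_dir: str | Path = "famrank_out"
    report_decimals: int = 2
    log_level: str = "INFO"


def run(config: RunConfig) -> RankingResult:
    """Execute the full pipeline and write report files.

    Writes into ``config.out_dir``: ``ranking.csv`` (condition_id,
    overall_index, rank, tie_flag; full precision), ``grade_masses.csv``
    (per-condition aggregated grade masses) and ``report.md`` (indices
    rounded to ``report_decimals``, top condition named, ties flagged).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if config.criteria_config is not None:
        criteria, grade_set = load_config(config.criteria_config)
    else:
        criteria, grade_set = default_criteria(), GradeSet()
    frame = read_records_csv(config.data)

    report = validate(frame, criteria)
    for issue in report.warnings:
        logger.warning("%s", issue.message)
    report.raise_if_fatal()

    result = rank_conditions(frame, criteria, grade_set, check_weights=False)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out / "ranking.csv", index=False)
    result.grade_masses.to_csv(out / "grade_masses.csv")
    (out / "report.md").write_text(_render_report(result, config.report_decimals),
                                   encoding="utf-8")
    return result


def _render_report(result: RankingResult, decimals: int = 2) -> str:
    table = result.table
    top = table.iloc[0]
    lines = ["# Overall performance ranking", ""]
    if bool(top["tie_flag"]):
        tied = table.loc[np.isclose(table["overall_index"], top["overall_index"]),
                         "condition_id"].tolist()
        lines.append(
            f"Top conditions (tied at index {top['overall_index']:.{decimals}f}): "
            + ", ".join(tied)
        )
    else:
        lines.append(
            f"Best condition: **{top['condition_id']}** "
            f"(overall performance index {top['overall_index']:.{decimals}f})"
        )
    lines += ["", "| rank | condition | overall index | tie |", "|---|---|---|---|"]
    for row in table.itertuples():
        lines.append(
            f"| {row.rank} | {row.condition_id} | "
            f"{row.overall_index:.{decimals}f} | {'yes' if row.tie_flag else ''} |"
        )
    lines.append("")
    return "\n".join(lines)
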