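"""End-to-end pipeline: simulate or ingest, score, classify, compare, report.

One call produces the study-shaped outputs: a labeled patient table, the
clinical-vs-biological contingency table, per-group biomarker summaries
with omnibus tests, the corrected pairwise tests, and a machine-readable
run manifest. Fully deterministic in simulate mode under a fixed seed.
"""

from __future__ import annotations

import importlib.metadata
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import io as mio
from .classify import Thresholds, classify_cohort
from .cohort import (
    BINARY_FLAGS,
    CONTINUOUS_VARIABLES,
    CohortConfig,
    GroupParams,
    default_group_params,
    generate_cohort,
)
from .exceptions import ConfigError
from .labels import UNCLASSIFIED, TABLE_LABEL_ORDER, DiagnosisLabel
from .scoring import add_overall_composite
from .stats import (
    CrossTab,
    GroupSummary,
    PairwiseResult,
    crosstab,
    pairwise_by_variable,
    pairwise_frame,
    summarize_groups,
    summary_frame,
)

__all__ = ["RunConfig", "ReportBundle", "ValidationIssue", "run_pipeline", "validate_table"]

logger = logging.getLogger(__name__)

#: Variables reported in the per-group summary (the study's summary table).
DEFAULT_SUMMARY_VARIABLES = ["age", "t_memory", "t_executive", "md_z", "mmp1", "mmp10", "ptau"]

_REPORT_GROUP_ORDER = ["LA", "MX", "SIVD", "AD", "CONTROL"]


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    mode: str = "simulate"  # "simulate" | "ingest"
    seed: int = 0
    table_path: str | Path | None = None  # required in ingest mode
    thresholds: Thresholds = field(default_factory=Thresholds)
    cohort: CohortConfig | None = None
    params: dict[DiagnosisLabel, GroupParams] | None = None
    classify_method: str = "dichotomy"
    summary_variables: list[str] = field(default_factory=lambda: list(DEFAULT_SUMMARY_VARIABLES))
    correction: str = "holm"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ConfigError(f"mode must be 'simulate' or 'ingest', got {self.mode!r}")
        if self.mode == "ingest" and self.table_path is None:
            raise ConfigError("ingest mode requires table_path")


@dataclass(frozen=True)
class ValidationIssue:
    column: str
    row: int | None  # None for table-level (schema) issues
    message: str


@dataclass
class ReportBundle:
    """Everything one pipeline run produces."""

    table: pd.DataFrame
    cross: CrossTab | None
    summaries: list[GroupSummary]
    pairwise: list[PairwiseResult]
    manifest: dict[str, Any]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_table(self.table, out / "labeled_table.csv")
        if self.cross is not None:
            self.cross.with_margins().to_csv(out / "crosstab.csv")
        summary_frame(self.summaries).to_csv(out / "group_summary.csv")
        pairwise_frame(self.pairwise).to_csv(out / "pairwise_tests.csv", index=False)
        mio.save_config(self.manifest, out / "manifest.yaml")


_RANGES: dict[str, tuple[float | None, float | None]] = dict(CONTINUOUS_VARIABLES)


def validate_table(table: pd.DataFrame, required: list[str] | None = None) -> list[ValidationIssue]:
    """Check a patient table against the record invariants.

    Returns a report-only issue list: schema issues (missing columns) carry
    ``row=None``; value issues name the offending row index.
    """
    if required is None:
        required = list(CONTINUOUS_VARIABLES) + list(BINARY_FLAGS)
    issues: list[ValidationIssue] = []
    for col in required:
        if col not in table.columns:
            issues.append(ValidationIssue(col, None, f"required column {col!r} is missing"))
    for col, (lo, hi) in _RANGES.items():
        if col not in table.columns:
            continue
        values = pd.to_numeric(table[col], errors="coerce")
        strict_lo = col in ("ptau", "ab_ratio")  # open lower/upper bounds
        for idx, v in values.items():
            if pd.isna(v):
                if not pd.isna(table.loc[idx, col]):
                    issues.append(ValidationIssue(col, int(idx), f"non-numeric value {table.loc[idx, col]!r}"))
                continue
            if not math.isfinite(v):
                issues.append(ValidationIssue(col, int(idx), f"non-finite value {v}"))
                continue
            if lo is not None and (v <= lo if strict_lo else v < lo):
                issues.append(ValidationIssue(col, int(idx), f"value {v} below {lo}"))
            if hi is not None and (v >= hi if strict_lo else v > hi):
                issues.append(ValidationIssue(col, int(idx), f"value {v} above {hi}"))
    return issues


def _report_group(row: pd.Series) -> str:
    if row.get("clinical_label") == DiagnosisLabel.CONTROL.value:
        return DiagnosisLabel.CONTROL.value
    return row["biological_label_predicted"]


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full stratification pipeline and assemble the report bundle."""
    if config.mode == "simulate":
        cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
        table = generate_cohort(cohort_cfg, config.params or default_group_params())
    else:
        table = mio.read_table(config.table_path)
        issues = validate_table(table, required=None)
        schema_issues = [i for i in issues if i.row is None]
        if schema_issues:
            raise ConfigError(
                "table failed validation: " + "; ".join(i.message for i in schema_issues)
            )

    table = add_overall_composite(table)
    labeled = classify_cohort(table, config.thresholds, method=config.classify_method)
    labeled["report_group"] = labeled.apply(_report_group, axis=1)

    # contingency table over patients (controls and unclassifiable rows excluded)
    cross = None
    if "clinical_label" in labeled.columns:
        order = [l.value for l in TABLE_LABEL_ORDER]
        mask = labeled["clinical_label"].isin(order) & labeled[
            "biological_label_predicted"
        ].isin(order)
        cross = crosstab(
            labeled.loc[mask, "clinical_label"],
            labeled.loc[mask, "biological_label_predicted"],
        )

    stats_table = labeled[labeled["report_group"] != UNCLASSIFIED]
    group_order = [g for g in _REPORT_GROUP_ORDER if g in set(stats_table["report_group"])]
    group_order += [g for g in dict.fromkeys(stats_table["report_group"]) if g not in group_order]
    variables = [v for v in config.summary_variables if v in stats_table.columns]
    summaries = summarize_groups(stats_table, variables, "report_group", group_order)
    pairwise = pairwise_by_variable(
        stats_table, variables, "report_group", correction=config.correction, group_order=group_order
    )

    try:
        version = importlib.metadata.version("mixstrat")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {
        "package": "mixstrat",
        "version": version,
        "mode": config.mode,
        "seed": config.seed,
        "classify_method": config.classify_method,
        "correction": config.correction,
        "thresholds": {
            k: getattr(config.thresholds, k) for k in Thresholds.__dataclass_fields__
        },
        "n_rows": int(len(labeled)),
        "n_unclassified": int((labeled["biological_label_predicted"] == UNCLASSIFIED).sum()),
        "group_sizes": (
            {k.value: v for k, v in (config.cohort or CohortConfig(seed=config.seed)).group_sizes.items()}
            if config.mode == "simulate"
            else None
        ),
        "summary_variables": variables,
    }
    return ReportBundle(table=labeled, cross=cross, summaries=summaries, pairwise=pairwise, manifest=manifest)
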