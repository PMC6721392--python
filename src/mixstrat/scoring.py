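"""Composite cognitive scoring and diffusivity z-scoring.

T-scores are standardized neuropsychological scores (population mean 50,
SD 10). Domain composites average the available tests within a cognitive
domain; the overall composite averages the available domain composites.
White-matter mean diffusivity (MD) is normalized against a control
reference so that normal is near zero and injured white matter sits in the
1–3 z range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import DegenerateReferenceError, InputError, MissingDataError

__all__ = [
    "DomainScores",
    "ControlReference",
    "CompositeResult",
    "domain_composite",
    "overall_composite",
    "fit_control_reference",
    "md_zscore",
    "add_overall_composite",
]

DOMAINS = ("memory", "executive", "attention", "language", "speed")


@dataclass(frozen=True)
class DomainScores:
    """Per-domain composite T-scores; ``None`` marks a missing domain."""

    memory: float | None = None
    executive: float | None = None
    attention: float | None = None
    language: float | None = None
    speed: float | None = None

    def present(self) -> dict[str, float]:
        out = {}
        for d in DOMAINS:
            v = getattr(self, d)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                out[d] = float(v)
        return out


@dataclass(frozen=True)
class ControlReference:
    """Control-sample mean/SD of the MD summary used for z-scoring."""

    md_mean: float
    md_sd: float
    n_controls: int

    def __post_init__(self) -> None:
        if self.md_sd <= 0:
            raise DegenerateReferenceError(f"md_sd must be positive, got {self.md_sd}")
        if self.n_controls < 2:
            raise DegenerateReferenceError(f"need >= 2 controls, got {self.n_controls}")


class CompositeResult(NamedTuple):
    score: float
    n_domains: int


def _finite(values: Iterable[float | None]) -> list[float]:
    out = []
    for v in values:
        if v is None:
            continue
        v = float(v)
        if math.isnan(v):
            continue
        if not math.isfinite(v):
            raise InputError(f"non-finite score {v}")
        out.append(v)
    return out


def domain_composite(test_tscores: Iterable[float | None], min_tests: int = 1) -> float:
    """Mean of the available test T-scores within one cognitive domain.

    Missing tests (``None``/NaN) are dropped; at least ``min_tests``
    non-missing scores are required.
    """
    scores = _finite(test_tscores)
    if len(scores) < max(min_tests, 1):
        raise MissingDataError(
            f"domain composite needs >= {max(min_tests, 1)} test scores, got {len(scores)}"
        )
    return float(np.mean(scores))


def overall_composite(domains: DomainScores) -> CompositeResult:
    """Mean of the available domain composites, with the contributing count."""
    present = domains.present()
    if not present:
        raise MissingDataError("all cognitive domains missing")
    return CompositeResult(float(np.mean(list(present.values()))), len(present))


def fit_control_reference(control_md_values: Iterable[float]) -> ControlReference:
    """Sample mean and SD (n-1 denominator) of control MD values."""
    values = np.asarray(_finite(control_md_values), dtype=float)
    if values.size < 2:
        raise DegenerateReferenceError(f"need >= 2 finite control values, got {values.size}")
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        raise DegenerateReferenceError("control MD values have zero spread")
    return ControlReference(md_mean=float(np.mean(values)), md_sd=sd, n_controls=int(values.size))


def md_zscore(md: float, ref: ControlReference) -> float:
    """Standardize an MD summary against the control reference."""
    if md is None or not math.isfinite(md):
        raise InputError(f"MD value must be finite, got {md}")
    return (float(md) - ref.md_mean) / ref.md_sd


def add_overall_composite(table: pd.DataFrame, out_column: str = "t_overall") -> pd.DataFrame:
    """Append the overall cognitive composite to a patient table.

    Averages whichever of the five domain columns (t_memory, t_executive,
    t_attention, t_language, t_speed) are present and non-missing per row;
    rows with no domain at all get NaN.
    """
    cols = [f"t_{d}" for d in DOMAINS if f"t_{d}" in table.columns]
    out = table.copy()
    out[out_column] = table[cols].mean(axis=1, skipna=True) if cols else np.nan
    return out
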