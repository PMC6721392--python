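"""Rule-based biological classification of dementia patients.

Two classifiers over the same biomarker record:

* **Double dichotomy** — two independent axes. The Alzheimer (CSF) axis is
  positive when phosphorylated tau is elevated and/or the amyloid-beta
  42/40 ratio is lowered; the vascular (DTI) axis is positive when the
  white-matter mean-diffusivity z-score is elevated. Both positive gives
  mixed dementia (MX); CSF only, AD; DTI only, SIVD; neither, LA. A
  documented infarct overrides everything to MI, which sits outside the
  four quadrants.
* **Feature-matrix matcher** — binarizes nine clinical/neuropsychological/
  MRI/CSF features and scores each candidate label by agreement with its
  expected +/- sign pattern, returning the best match.

All numeric cut-points are package defaults (the qualitative high/low
axes carry no published thresholds) and live in :class:`Thresholds`, so
they can be overridden from configuration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields

import pandas as pd

from .exceptions import ConfigError, MissingDataError
from .labels import UNCLASSIFIED, DiagnosisLabel

__all__ = [
    "Thresholds",
    "FeatureVector",
    "FeatureMatrix",
    "ad_axis_positive",
    "vascular_axis_positive",
    "classify_dichotomy",
    "feature_vector",
    "classify_feature_matrix",
    "classify_cohort",
]

logger = logging.getLogger(__name__)

AD_AXIS_RULES = ("either", "both", "ptau_only", "amyloid_only")


@dataclass(frozen=True)
class Thresholds:
    """Configurable cut-points for feature positivity and the two axes.

    Boundary convention: a value exactly at a cut is positive (``>=`` for
    "high" cuts, ``<=`` for "low" cuts).
    """

    ptau_high: float = 68.0  # pg/mL
    ab_ratio_low: float = 0.07
    md_z_high: float = 2.0
    t_memory_low: float = 40.0
    t_executive_low: float = 40.0
    albumin_index_high: float = 6.5
    ad_axis_rule: str = "either"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "ad_axis_rule":
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ConfigError(f"threshold {f.name} must be finite, got {v}")
        if self.ad_axis_rule not in AD_AXIS_RULES:
            raise ConfigError(
                f"ad_axis_rule must be one of {AD_AXIS_RULES}, got {self.ad_axis_rule!r}"
            )


FEATURE_NAMES = (
    "hyperreflexia",
    "imbalance",
    "executive_deficit",
    "memory_deficit",
    "wmh_flair",
    "md_dti_high",
    "amyloid_positive",
    "ptau_positive",
    "albumin_index_high",
)


@dataclass(frozen=True)
class FeatureVector:
    """Nine binarized diagnostic features for one patient."""

    hyperreflexia: bool
    imbalance: bool
    executive_deficit: bool
    memory_deficit: bool
    wmh_flair: bool
    md_dti_high: bool
    amyloid_positive: bool
    ptau_positive: bool
    albumin_index_high: bool

    def as_tuple(self) -> tuple[bool, ...]:
        return tuple(getattr(self, n) for n in FEATURE_NAMES)


# Expected sign of each feature per diagnosis (the published feature matrix):
# True = "+" (feature present in that diagnosis), False = "-".
_DEFAULT_SIGNS: dict[DiagnosisLabel, tuple[bool, ...]] = {
    #                 hyper  imbal  exec   mem    wmh    md     amyl   ptau   albumin
    DiagnosisLabel.SIVD: (True, True, True, False, True, True, False, False, True),
    DiagnosisLabel.AD: (False, False, False, True, False, False, True, True, False),
    DiagnosisLabel.MX: (True, True, False, True, True, True, True, True, True),
    DiagnosisLabel.LA: (False, False, False, False, True, False, False, False, False),
}

#: Tie-break precedence in the feature matcher: the dual-pathology label
#: first (most treatment-relevant), then the vascular, then AD, then LA.
TIE_PRECEDENCE = (DiagnosisLabel.MX, DiagnosisLabel.SIVD, DiagnosisLabel.AD, DiagnosisLabel.LA)


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-label expected sign for each of the nine features."""

    signs: dict[DiagnosisLabel, tuple[bool, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_SIGNS)
    )

    def __post_init__(self) -> None:
        for label, row in self.signs.items():
            if len(row) != len(FEATURE_NAMES):
                raise ConfigError(f"sign row for {label} must have {len(FEATURE_NAMES)} entries")


def _require(record, name: str) -> float:
    value = record[name] if isinstance(record, (dict, pd.Series)) else getattr(record, name)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingDataError(f"required field {name!r} is missing")
    return value


def ad_axis_positive(record, th: Thresholds) -> bool:
    """Alzheimer-protein axis: elevated Ptau and/or lowered amyloid 42/40 ratio."""
    rule = th.ad_axis_rule
    if rule in ("either", "both", "ptau_only"):
        ptau_pos = float(_require(record, "ptau")) >= th.ptau_high
    if rule in ("either", "both", "amyloid_only"):
        amyloid_pos = float(_require(record, "ab_ratio")) <= th.ab_ratio_low
    if rule == "either":
        return ptau_pos or amyloid_pos
    if rule == "both":
        return ptau_pos and amyloid_pos
    return ptau_pos if rule == "ptau_only" else amyloid_pos


def vascular_axis_positive(record, th: Thresholds) -> bool:
    """Vascular axis: elevated white-matter mean-diffusivity z-score."""
    return float(_require(record, "md_z")) >= th.md_z_high


def classify_dichotomy(record, th: Thresholds) -> DiagnosisLabel:
    """Assign a biological label from the two axes, with the infarct override."""
    if bool(_require(record, "infarct")):
        return DiagnosisLabel.MI
    ad_pos = ad_axis_positive(record, th)
    vasc_pos = vascular_axis_positive(record, th)
    if ad_pos and vasc_pos:
        return DiagnosisLabel.MX
    if ad_pos:
        return DiagnosisLabel.AD
    if vasc_pos:
        return DiagnosisLabel.SIVD
    return DiagnosisLabel.LA


def feature_vector(record, th: Thresholds) -> FeatureVector:
    """Binarize a patient record into the nine diagnostic features."""
    return FeatureVector(
        hyperreflexia=bool(_require(record, "hyperreflexia")),
        imbalance=bool(_require(record, "imbalance")),
        executive_deficit=float(_require(record, "t_executive")) <= th.t_executive_low,
        memory_deficit=float(_require(record, "t_memory")) <= th.t_memory_low,
        wmh_flair=bool(_require(record, "wmh_present")),
        md_dti_high=vascular_axis_positive(record, th),
        amyloid_positive=float(_require(record, "ab_ratio")) <= th.ab_ratio_low,
        ptau_positive=float(_require(record, "ptau")) >= th.ptau_high,
        albumin_index_high=float(_require(record, "albumin_index")) >= th.albumin_index_high,
    )


def classify_feature_matrix(
    fv: FeatureVector, fm: FeatureMatrix | None = None
) -> tuple[DiagnosisLabel, dict[DiagnosisLabel, int]]:
    """Best-matching label by feature agreement, with per-label scores.

    score(label) = number of the nine features whose observed value equals
    the label's expected sign. Ties go to the earlier label in
    :data:`TIE_PRECEDENCE`.
    """
    if fm is None:
        fm = FeatureMatrix()
    observed = fv.as_tuple()
    scores = {
        label: sum(o == e for o, e in zip(observed, expected))
        for label, expected in fm.signs.items()
    }
    best = max(scores.values())
    order = [l for l in TIE_PRECEDENCE if l in scores] + [
        l for l in scores if l not in TIE_PRECEDENCE
    ]
    winner = next(l for l in order if scores[l] == best)
    return winner, scores


_DICHOTOMY_COLUMNS = ("ptau", "ab_ratio", "md_z", "infarct")
_FEATURE_COLUMNS = (
    "hyperreflexia",
    "imbalance",
    "t_executive",
    "t_memory",
    "wmh_present",
    "md_z",
    "ab_ratio",
    "ptau",
    "albumin_index",
)


def classify_cohort(
    table: pd.DataFrame,
    th: Thresholds | None = None,
    method: str = "dichotomy",
    fm: FeatureMatrix | None = None,
) -> pd.DataFrame:
    """Classify every row of a patient table.

    Adds ``biological_label_predicted``; the feature-matrix method also adds
    per-label ``score_<LABEL>`` columns. Rows with missing required fields
    become ``UNCLASSIFIED`` (reason logged and recorded in
    ``unclassified_reason``).
    """
    if th is None:
        th = Thresholds()
    if method not in ("dichotomy", "feature_matrix"):
        raise ConfigError(f"unknown method {method!r}")
    required = _DICHOTOMY_COLUMNS if method == "dichotomy" else _FEATURE_COLUMNS
    out = table.copy()
    missing_cols = [c for c in required if c not in table.columns]

    predictions: list[str] = []
    reasons: list[str] = []
    score_rows: list[dict[DiagnosisLabel, int] | None] = []
    for _, row in table.iterrows():
        try:
            if missing_cols:
                raise MissingDataError(f"missing columns: {missing_cols}")
            if method == "dichotomy":
                label = classify_dichotomy(row, th)
                scores = None
            else:
                label, scores = classify_feature_matrix(feature_vector(row, th), fm)
            predictions.append(label.value)
            reasons.append("")
            score_rows.append(scores)
        except MissingDataError as exc:
            predictions.append(UNCLASSIFIED)
            reasons.append(str(exc))
            score_rows.append(None)
    n_unclassified = sum(p == UNCLASSIFIED for p in predictions)
    if n_unclassified:
        logger.warning("%d of %d rows unclassified", n_unclassified, len(predictions))

    out["biological_label_predicted"] = pd.Series(predictions, index=table.index, dtype=object)
    out["unclassified_reason"] = pd.Series(reasons, index=table.index, dtype=object)
    if method == "feature_matrix":
        labels = (fm or FeatureMatrix()).signs.keys()
        for label in labels:
            out[f"score_{label.value}"] = [
                (s[label] if s is not None else pd.NA) for s in score_rows
            ]
    return out
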