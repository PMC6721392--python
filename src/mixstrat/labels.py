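"""Diagnostic label vocabulary.

Five patient categories plus cognitively normal controls:

* ``SIVD`` — subcortical ischemic vascular disease (Binswanger-type
  small-vessel dementia with prominent white-matter injury).
* ``AD``   — Alzheimer's disease.
* ``MX``   — mixed dementia: Alzheimer protein pathology *and* vascular
  white-matter injury in the same patient.
* ``MI``   — dementia from multiple (large-vessel/strategic) infarcts.
* ``LA``   — leukoaraiosis: FLAIR white-matter hyperintensities without
  microstructural damage or cognitive abnormality.
* ``CONTROL`` — cognitively normal reference subjects.
"""

from __future__ import annotations

import enum


class DiagnosisLabel(str, enum.Enum):
    """Diagnostic category used for both clinical and biological labels."""

    SIVD = "SIVD"
    AD = "AD"
    MX = "MX"
    MI = "MI"
    LA = "LA"
    CONTROL = "CONTROL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Column/row order of the clinical-vs-biological contingency table.
TABLE_LABEL_ORDER: tuple[DiagnosisLabel, ...] = (
    DiagnosisLabel.SIVD,
    DiagnosisLabel.AD,
    DiagnosisLabel.MX,
    DiagnosisLabel.MI,
    DiagnosisLabel.LA,
)

#: Sentinel used by cohort-level classification for rows with missing data.
UNCLASSIFIED = "UNCLASSIFIED"
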