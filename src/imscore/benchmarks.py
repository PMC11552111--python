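"""Published cohort marginals used for desk validation.

A published end-of-therapy PET study of primary CNS lymphoma (38-patient
PET/CT cohort, 45-patient PET/MR cohort) prints, per cohort and score
dichotomy, the counts of events and score-positive patients together with
sensitivity/specificity/PPV/NPV/AUC.  Those marginals plus one anchor metric
determine the full 2x2 table (:func:`imscore.diagnostics.reconstruct_contingency`),
letting the remaining printed metrics be recomputed rather than trusted.
The same study's cohort-characteristic tables provide 2x2 counts for
chi-square comparisons.  All values here are transcribed inputs, not outputs
of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DiagnosticColumn", "DIAGNOSTIC_COLUMNS", "CHI_SQUARE_TABLES",
           "REFERENCE_SUV_STATS", "IMS_COUNTS"]


@dataclass(frozen=True)
class DiagnosticColumn:
    """Marginals of one printed diagnostic column (a score dichotomy x endpoint)."""

    key: str
    cohort: str  # "PET_CT" | "PET_MR"
    scale: str  # "DS" | "IMS"
    positive_rule: str  # "4-5" | "5"
    endpoint: str  # "PFS" | "OS"
    n: int
    events: int
    positives: int
    anchor_sensitivity: float  # printed, percent


#: One entry per printed diagnostic column.  The DS 1-4 vs 5 dichotomy has
#: the same positive set as DS 1-3 vs 4-5 in the source cohort (no DS 4
#: patients), hence identical marginals.
DIAGNOSTIC_COLUMNS: tuple[DiagnosticColumn, ...] = (
    DiagnosticColumn("petct_ds45_pfs", "PET_CT", "DS", "4-5", "PFS", 38, 12, 5, 41.7),
    DiagnosticColumn("petct_ds5_pfs", "PET_CT", "DS", "5", "PFS", 38, 12, 5, 41.7),
    DiagnosticColumn("petct_ims45_pfs", "PET_CT", "IMS", "4-5", "PFS", 38, 12, 10, 66.7),
    DiagnosticColumn("petct_ims5_pfs", "PET_CT", "IMS", "5", "PFS", 38, 12, 5, 41.7),
    DiagnosticColumn("petmr_ims45_pfs", "PET_MR", "IMS", "4-5", "PFS", 45, 8, 14, 87.5),
    DiagnosticColumn("petmr_ims5_pfs", "PET_MR", "IMS", "5", "PFS", 45, 8, 5, 62.5),
    DiagnosticColumn("petct_ds45_os", "PET_CT", "DS", "4-5", "OS", 38, 7, 5, 57.1),
    DiagnosticColumn("petct_ds5_os", "PET_CT", "DS", "5", "OS", 38, 7, 5, 57.1),
    DiagnosticColumn("petct_ims45_os", "PET_CT", "IMS", "4-5", "OS", 38, 7, 10, 85.7),
    DiagnosticColumn("petct_ims5_os", "PET_CT", "IMS", "5", "OS", 38, 7, 5, 57.1),
    DiagnosticColumn("petmr_ims45_os", "PET_MR", "IMS", "4-5", "OS", 45, 3, 14, 66.7),
    DiagnosticColumn("petmr_ims5_os", "PET_MR", "IMS", "5", "OS", 45, 3, 5, 33.3),
)

#: Cohort-characteristic 2x2 counts (rows: category, columns: PET/CT, PET/MR).
CHI_SQUARE_TABLES: dict[str, list[list[int]]] = {
    "ielsg": [[20, 14], [18, 31]],   # IELSG 0-1 vs 2-3 per cohort
    "gender": [[20, 24], [18, 21]],  # male vs female per cohort
}

#: Reference-structure SUVmax statistics (mean, SD) used as generator defaults.
REFERENCE_SUV_STATS: dict[str, tuple[float, float]] = {
    "gm": (9.45, 2.01), "liver": (2.96, 0.42), "wm": (2.81, 0.58),
    "mediastinum": (1.80, 0.36), "csf": (1.50, 0.34),
}

#: IMS level counts per cohort (levels 1..5).
IMS_COUNTS: dict[str, tuple[int, ...]] = {
    "PET_CT": (8, 9, 11, 5, 5),
    "PET_MR": (10, 9, 12, 9, 5),
}
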