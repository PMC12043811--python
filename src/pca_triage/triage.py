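"""Six-way biopsy-recommendation categories and the hybrid decision protocol.

Each case's CAD outcome is summarised by the pair (number of aggressive
lesions annotated, number of lesions the CAD claims), which falls in exactly
one of six categories:

* ``CORRECT_AVOIDED``   — no lesions present, none detected: an unnecessary
  biopsy is correctly avoided;
* ``CORRECT``           — lesions present, count estimated exactly;
* ``OVERESTIMATE``      — lesions present, count overestimated;
* ``OVERESTIMATE_UNNECESSARY`` — no lesions present but some detected: an
  unnecessary biopsy is recommended;
* ``UNDERESTIMATE``     — two or more present, between one and the true
  count (exclusive) detected;
* ``DANGEROUS_UNDERESTIMATE`` — lesions present but none detected: a
  necessary biopsy would be avoided.

The literal category list covers the none-detected case only for two or more
lesions; a missed solitary lesion is by default also a dangerous
underestimate (it avoids a necessary biopsy); ``strict_categories=True``
restores the literal behaviour and reports pair (1, 0) as uncategorised.

The hybrid protocol combines a radiologist read with the CAD recommendation:
a biopsy is performed iff *both* recommend it — the radiologist gates the
decision and the CAD can only remove biopsies, never add them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .candidates import CaseDetection

__all__ = [
    "TriageCategory",
    "TriageRecord",
    "TriageSummary",
    "categorize",
    "cad_recommendation",
    "hybrid_decision",
    "simulate_protocol",
    "relative_frequencies",
]


class TriageCategory(str, Enum):
    CORRECT_AVOIDED = "correct_avoided_biopsy"
    CORRECT = "correct"
    OVERESTIMATE = "overestimate"
    OVERESTIMATE_UNNECESSARY = "overestimate_unnecessary_biopsy"
    UNDERESTIMATE = "underestimate"
    DANGEROUS_UNDERESTIMATE = "dangerous_underestimate"
    UNCATEGORIZED = "uncategorized"  # only under strict_categories for (1, 0)


@dataclass
class TriageRecord:
    case_id: str
    n_annotated: int
    n_detected: int
    category: TriageCategory
    radiologist: bool
    cad: bool
    hybrid_biopsy: bool
    truth_aggressive: bool

    def __post_init__(self) -> None:
        if self.hybrid_biopsy and not (self.radiologist and self.cad):
            raise ValueError("hybrid biopsy requires both recommendations")


@dataclass
class TriageSummary:
    """Cohort-level tallies of the simulated decision protocol.

    Percentages are reported under two denominators: the whole cohort
    (``pct_of_cohort``) and, for the biopsy-related categories, the relevant
    truth subset (``pct_of_negatives`` / ``pct_of_positives``).
    """

    n_cases: int
    category_counts: dict[TriageCategory, int]
    category_pct: dict[TriageCategory, float]
    count_matrix: pd.DataFrame  # annotated (rows) x detected (cols)
    biopsies_radiologist: int
    biopsies_hybrid: int
    avoided_unnecessary: int  # radiologist yes, CAD no, truth negative
    dangerous_avoidances: int  # radiologist yes, CAD no, truth positive
    avoided_unnecessary_pct_of_cohort: float
    avoided_unnecessary_pct_of_negatives: float
    unnecessary_biopsies: int  # hybrid biopsy on a truth-negative case
    unnecessary_biopsies_pct_of_cohort: float
    unnecessary_biopsies_pct_of_negatives: float
    records: list[TriageRecord] = field(default_factory=list)


def categorize(
    n_annotated: int, n_detected: int, strict_categories: bool = False
) -> TriageCategory:
    """Assign the six-way category to one (annotated, detected) pair."""
    if n_annotated < 0 or n_detected < 0:
        raise ValueError("lesion counts must be non-negative")
    if n_annotated == 0:
        return (
            TriageCategory.CORRECT_AVOIDED
            if n_detected == 0
            else TriageCategory.OVERESTIMATE_UNNECESSARY
        )
    if n_detected == n_annotated:
        return TriageCategory.CORRECT
    if n_detected > n_annotated:
        return TriageCategory.OVERESTIMATE
    if n_detected == 0:
        if n_annotated >= 2:
            return TriageCategory.DANGEROUS_UNDERESTIMATE
        return (
            TriageCategory.UNCATEGORIZED
            if strict_categories
            else TriageCategory.DANGEROUS_UNDERESTIMATE
        )
    return TriageCategory.UNDERESTIMATE


def cad_recommendation(det: CaseDetection) -> bool:
    """CAD recommends a biopsy iff it retained at least one candidate.

    Equivalent to case probability clearing the confidence threshold, since
    every retained candidate's confidence does.
    """
    return det.n_detected >= 1


def hybrid_decision(radiologist: bool, cad: bool) -> bool:
    """Biopsy performed iff both the radiologist and the CAD recommend it."""
    return bool(radiologist) and bool(cad)


def relative_frequencies(
    counts: "dict | int", denominator: int, decimals: int = 2
) -> "dict[str, float] | float":
    """Percentages 100*count/denominator, rounded half-even.

    Accepts a single count or a mapping of counts.
    """
    if denominator < 1:
        raise ValueError("denominator must be >= 1")

    def pct(c: int) -> float:
        return float(np.round(100.0 * c / denominator, decimals))

    if isinstance(counts, dict):
        return {k: pct(v) for k, v in counts.items()}
    return pct(counts)


def simulate_protocol(
    detections: list[CaseDetection],
    radiologist_reads: dict[str, bool],
    truths: dict[str, bool],
    strict_categories: bool = False,
    decimals: int = 2,
) -> TriageSummary:
    """Simulate the hybrid radiologist+CAD protocol over a cohort.

    ``truths`` maps case id to whether the case truly harbours aggressive
    disease. Tallies the six-way categories, the annotated x detected count
    matrix, biopsies under radiologist-alone vs hybrid, unnecessary biopsies
    avoided (radiologist yes, CAD no, truth negative) and dangerous
    avoidances (radiologist yes, CAD no, truth positive).
    """
    ids = [d.case_id for d in detections]
    missing = (set(ids) - set(radiologist_reads)) | (set(ids) - set(truths))
    if missing or len(set(ids)) != len(ids):
        raise ValueError(f"case-id mismatch between inputs: {sorted(missing)}")

    records = []
    for det in detections:
        rad = bool(radiologist_reads[det.case_id])
        cad = cad_recommendation(det)
        records.append(
            TriageRecord(
                case_id=det.case_id,
                n_annotated=det.n_annotated,
                n_detected=det.n_detected,
                category=categorize(det.n_annotated, det.n_detected, strict_categories),
                radiologist=rad,
                cad=cad,
                hybrid_biopsy=hybrid_decision(rad, cad),
                truth_aggressive=bool(truths[det.case_id]),
            )
        )

    n = len(records)
    counts = {cat: 0 for cat in TriageCategory}
    for r in records:
        counts[r.category] += 1
    if not strict_categories:
        counts.pop(TriageCategory.UNCATEGORIZED)

    max_ann = max((r.n_annotated for r in records), default=0)
    max_det = max((r.n_detected for r in records), default=0)
    mat = np.zeros((max_ann + 1, max_det + 1), dtype=int)
    for r in records:
        mat[r.n_annotated, r.n_detected] += 1
    count_matrix = pd.DataFrame(
        mat,
        index=pd.Index(range(max_ann + 1), name="n_annotated"),
        columns=pd.Index(range(max_det + 1), name="n_detected"),
    )

    n_neg = sum(not r.truth_aggressive for r in records)
    avoided = sum(
        r.radiologist and not r.cad and not r.truth_aggressive for r in records
    )
    dangerous = sum(r.radiologist and not r.cad and r.truth_aggressive for r in records)
    unnecessary = sum(r.hybrid_biopsy and not r.truth_aggressive for r in records)

    def _pct(c: int, d: int) -> float:
        return relative_frequencies(c, d, decimals) if d >= 1 else float("nan")

    return TriageSummary(
        n_cases=n,
        category_counts=counts,
        category_pct={k: _pct(v, n) for k, v in counts.items()},
        count_matrix=count_matrix,
        biopsies_radiologist=sum(r.radiologist for r in records),
        biopsies_hybrid=sum(r.hybrid_biopsy for r in records),
        avoided_unnecessary=avoided,
        dangerous_avoidances=dangerous,
        avoided_unnecessary_pct_of_cohort=_pct(avoided, n),
        avoided_unnecessary_pct_of_negatives=_pct(avoided, n_neg),
        unnecessary_biopsies=unnecessary,
        unnecessary_biopsies_pct_of_cohort=_pct(unnecessary, n),
        unnecessary_biopsies_pct_of_negatives=_pct(unnecessary, n_neg),
        records=records,
    )
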