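"""Lesion-candidate extraction and lesion-level detection evaluation.

The evaluation protocol applied to a detector's probability map:

1. threshold the map at 10%, producing soft blobs (all thresholds are
   inclusive: a value exactly at the threshold is kept);
2. take connected components (26-neighbourhood by default) as lesion
   candidates, each with confidence = maximum probability in the component;
3. discard candidates whose confidence is below 10%;
4. discard candidates with less than 10% of their volume inside the prostate
   gland (extra-prostatic findings, while still tolerating extracapsular
   extension);
5. assign the retained candidates one-to-one to the aggressive (ISUP >= 2)
   ground-truth lesions by maximising total voxel overlap (linear sum
   assignment; zero-overlap pairs are never matched);
6. a matched candidate is a hit only if it covers at least 10% of its
   assigned lesion — locating some *other* lesion in the same case does not
   count.

All four default thresholds are 0.10 and configurable via
:class:`DetectionConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .errors import GridMismatchError
from .phantom import AGGRESSIVE_ISUP, StudyCase
from .preprocess import ImageVolume

__all__ = [
    "DetectionConfig",
    "LesionCandidate",
    "CaseDetection",
    "threshold_map",
    "extract_candidates",
    "filter_confidence",
    "filter_gland_overlap",
    "assign_candidates",
    "score_hits",
    "run_detection",
]

RETAINED = "retained"
BELOW_CONFIDENCE = "below_confidence"
EXTRA_PROSTATIC = "extra_prostatic"


class DetectionConfig(BaseModel):
    """Thresholds and conventions of the candidate-selection protocol."""

    voxel_threshold: float = Field(default=0.10, gt=0.0, lt=1.0)
    confidence_threshold: float = Field(default=0.10, gt=0.0, lt=1.0)
    gland_overlap_threshold: float = Field(default=0.10, gt=0.0, lt=1.0)
    hit_threshold: float = Field(default=0.10, gt=0.0, lt=1.0)
    connectivity: int = Field(default=3, ge=1, le=3)  # 3 = full 26-neighbourhood
    # denominator of the 10%-intersection hit rule: the annotated lesion's
    # volume ("lesion", default) or the candidate's own volume ("candidate")
    hit_denominator: str = "lesion"
    # whether ISUP-1 annotated lesions take part in assignment as distractors
    include_nonaggressive_gt: bool = False


@dataclass
class LesionCandidate:
    """A connected component of the thresholded probability map."""

    candidate_id: int
    indices: np.ndarray  # flat voxel indices into the map grid
    confidence: float
    volume_mm3: float
    gland_fraction: float = float("nan")
    matched_gt: int | None = None
    hit_fraction: float = 0.0
    status: str = RETAINED
    hit: bool = False

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)


@dataclass
class CaseDetection:
    """Per-case outcome of the detection-evaluation protocol.

    ``n_detected`` counts retained candidates (the CAD's lesion count claim),
    not hit lesions, so over-detection is expressible. ``case_probability``
    is the maximum retained confidence (0 with no retained candidate) and
    drives the biopsy recommendation.
    """

    case_id: str
    n_annotated: int
    n_detected: int
    n_gt_hit: int
    n_hit_candidates: int = 0
    case_probability: float = 0.0
    candidates: list[LesionCandidate] = field(default_factory=list)
    pred_mask: np.ndarray | None = None
    empty_aggressive_label: bool = False  # aggressive case with an empty lesion mask

    def __post_init__(self) -> None:
        if self.n_gt_hit > self.n_annotated or self.n_gt_hit > self.n_detected:
            raise ValueError("n_gt_hit cannot exceed n_annotated or n_detected")
        if not 0.0 <= self.case_probability <= 1.0:
            raise ValueError("case probability must lie in [0, 1]")


def threshold_map(prob_map: ImageVolume, t: float) -> np.ndarray:
    """Boolean support of voxels with probability >= t (inclusive)."""
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {t}")
    values = prob_map.values
    if values.min() < 0.0 or values.max() > 1.0:
        raise ValueError("probability map values must lie in [0, 1]")
    return values >= t


def extract_candidates(
    support: np.ndarray, prob_map: ImageVolume, connectivity: int = 3
) -> list[LesionCandidate]:
    """Connected components of the support as candidates.

    Each candidate carries confidence = max probability over its voxels and
    volume = voxel count x voxel volume. Components use the requested 3D
    connectivity (1=6, 2=18, 3=26 neighbours).
    """
    if support.shape != prob_map.shape:
        raise GridMismatchError("support and probability map shapes differ")
    structure = ndimage.generate_binary_structure(3, connectivity)
    labeled, n = ndimage.label(support, structure=structure)
    flat_labels = labeled.ravel()
    flat_probs = prob_map.values.ravel()
    out = []
    for k in range(1, n + 1):
        idx = np.flatnonzero(flat_labels == k)
        out.append(
            LesionCandidate(
                candidate_id=k,
                indices=idx,
                confidence=float(flat_probs[idx].max()),
                volume_mm3=idx.size * prob_map.voxel_volume_mm3,
            )
        )
    return out


def filter_confidence(
    cands: list[LesionCandidate], t: float
) -> tuple[list[LesionCandidate], list[LesionCandidate]]:
    """Partition candidates into (kept, excluded) by confidence >= t."""
    kept, dropped = [], []
    for c in cands:
        if c.confidence >= t:
            kept.append(c)
        else:
            c.status = BELOW_CONFIDENCE
            dropped.append(c)
    return kept, dropped


def filter_gland_overlap(
    cands: list[LesionCandidate], gland_mask: np.ndarray, t: float
) -> tuple[list[LesionCandidate], list[LesionCandidate]]:
    """Partition candidates by the fraction of their own volume inside the gland.

    Fraction = |support ∩ gland| / |support|; candidates below ``t`` are
    flagged extra-prostatic. An empty gland mask removes every candidate
    (with a warning).
    """
    flat_gland = gland_mask.ravel().astype(bool)
    if not flat_gland.any():
        warnings.warn("empty gland mask: all candidates classified extra-prostatic")
    kept, dropped = [], []
    for c in cands:
        c.gland_fraction = float(flat_gland[c.indices].sum()) / c.n_voxels
        if c.gland_fraction >= t:
            kept.append(c)
        else:
            c.status = EXTRA_PROSTATIC
            dropped.append(c)
    return kept, dropped


def _overlap_matrix(
    cands: list[LesionCandidate], gt_flat: np.ndarray, gt_labels: list[int]
) -> np.ndarray:
    mat = np.zeros((len(cands), len(gt_labels)), dtype=np.int64)
    for i, c in enumerate(cands):
        vals = gt_flat[c.indices]
        for j, lab in enumerate(gt_labels):
            mat[i, j] = int((vals == lab).sum())
    return mat


def assign_candidates(
    cands: list[LesionCandidate], gt_instance_map: np.ndarray, gt_labels: list[int] | None = None
) -> dict[int, int]:
    """Optimal one-to-one candidate-to-lesion assignment by voxel overlap.

    Maximises total overlapping voxels with a linear sum assignment; pairs
    with zero overlap are dropped afterwards, so candidates overlapping no
    lesion stay unmatched (false positives) and lesions with no overlapping
    candidate stay unmatched (misses). Returns ``{candidate_id: gt_label}``
    and records ``matched_gt`` on each candidate.
    """
    if gt_labels is None:
        gt_labels = sorted(int(v) for v in np.unique(gt_instance_map) if v > 0)
    for c in cands:
        c.matched_gt = None
    if not cands or not gt_labels:
        return {}
    gt_flat = gt_instance_map.ravel()
    overlap = _overlap_matrix(cands, gt_flat, gt_labels)
    rows, cols = linear_sum_assignment(overlap, maximize=True)
    matching = {}
    for i, j in zip(rows, cols):
        if overlap[i, j] > 0:
            cands[i].matched_gt = gt_labels[j]
            matching[cands[i].candidate_id] = gt_labels[j]
    return matching


def score_hits(
    cands: list[LesionCandidate],
    gt_instance_map: np.ndarray,
    t_hit: float,
    denominator: str = "lesion",
) -> set[int]:
    """Score each matched candidate against its assigned lesion only.

    A candidate is a hit iff its overlap with its assigned lesion, divided by
    that lesion's voxel count (default) or by the candidate's own voxel count
    (``denominator='candidate'``), is at least ``t_hit``. Returns the set of
    detected ground-truth labels.
    """
    if denominator not in ("lesion", "candidate"):
        raise ValueError("denominator must be 'lesion' or 'candidate'")
    gt_flat = gt_instance_map.ravel()
    detected: set[int] = set()
    for c in cands:
        c.hit = False
        c.hit_fraction = 0.0
        if c.matched_gt is None:
            continue
        inter = int((gt_flat[c.indices] == c.matched_gt).sum())
        denom = (
            int((gt_flat == c.matched_gt).sum()) if denominator == "lesion" else c.n_voxels
        )
        if denom == 0:
            continue
        c.hit_fraction = inter / denom
        if c.hit_fraction >= t_hit:
            c.hit = True
            detected.add(int(c.matched_gt))
    return detected


def run_detection(
    case: StudyCase, prob_map: ImageVolume, cfg: DetectionConfig | None = None
) -> CaseDetection:
    """Run the full candidate-selection protocol for one case.

    Only aggressive (ISUP >= 2) annotated lesions count as ground truth, both
    for ``n_annotated`` and for hits; ISUP-1 lesions can be included as
    assignment distractors via ``cfg.include_nonaggressive_gt`` but never
    count as annotated. An aggressive case whose lesion mask is empty is
    valid input and flagged, not an error.
    """
    cfg = cfg or DetectionConfig()
    if not case.lesions.same_grid(prob_map) or case.gland.shape != prob_map.shape:
        raise GridMismatchError("probability map must share the case grid")

    support = threshold_map(prob_map, cfg.voxel_threshold)
    cands = extract_candidates(support, prob_map, cfg.connectivity)
    cands, _ = filter_confidence(cands, cfg.confidence_threshold)
    cands, _ = filter_gland_overlap(
        cands, case.gland.values, cfg.gland_overlap_threshold
    )

    agg_labels = case.aggressive_labels()
    if cfg.include_nonaggressive_gt:
        assign_labels = sorted(case.lesion_isup)
    else:
        assign_labels = agg_labels
    assign_candidates(cands, case.lesions.values, assign_labels)
    # matches to non-aggressive distractors do not score
    for c in cands:
        if c.matched_gt is not None and c.matched_gt not in agg_labels:
            c.matched_gt = None
    detected_labels = score_hits(
        cands, case.lesions.values, cfg.hit_threshold, cfg.hit_denominator
    )

    pred = np.zeros(prob_map.shape, dtype=bool)
    for c in cands:
        pred.ravel()[c.indices] = True

    return CaseDetection(
        case_id=case.case_id,
        n_annotated=len(agg_labels),
        n_detected=len(cands),
        n_gt_hit=len(detected_labels & set(agg_labels)),
        n_hit_candidates=sum(c.hit for c in cands),
        case_probability=max((c.confidence for c in cands), default=0.0),
        candidates=cands,
        pred_mask=pred,
        empty_aggressive_label=case.is_aggressive and not case.aggressive_mask().any(),
    )
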