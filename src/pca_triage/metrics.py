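"""Segmentation and detection metrics plus cohort descriptive analytics.

Overlap and surface metrics follow the conventions of the common medical
segmentation evaluation stack:

* Dice = 2|A∩B| / (|A|+|B|);
* Hausdorff distance (HD) = max of the two directed maximum surface
  distances, in mm (classical maximum; a percentile variant is available);
* ASSD = average of the two directed *mean* surface distances, in mm;
* RAVD = (|pred| − |gt|) / |gt|, signed; report abs() where the magnitude is
  wanted.

Surfaces are boundary voxels: mask voxels with at least one background
neighbour under 6-connectivity; distances are Euclidean between boundary
voxel centres with physical spacing applied.

Detection performance is pooled over a cohort at the lesion level:
recall = Σ hit lesions / Σ annotated lesions and
precision = Σ hit candidates / Σ retained candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .candidates import CaseDetection

__all__ = [
    "SegmentationMetrics",
    "CohortTable",
    "dice",
    "hausdorff",
    "assd",
    "ravd",
    "segmentation_metrics",
    "pooled_recall_precision",
    "component_analysis",
    "stratify_by_size",
    "cohort_table",
    "round_report",
]


@dataclass
class SegmentationMetrics:
    dice: float
    hausdorff_mm: float
    assd_mm: float
    ravd: float


@dataclass
class CohortTable:
    """Counts/proportions per ISUP x cohort x split, and per scanner."""

    by_isup: pd.DataFrame
    by_scanner: pd.DataFrame


def round_report(x: float, decimals: int = 2) -> float:
    """Half-even rounding used for report parity with printed tables."""
    return float(np.round(x, decimals))


def _check_masks(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    return a, b


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap; NaN when both masks are empty (excluded from averages)."""
    pred, gt = _check_masks(pred, gt)
    denom = int(pred.sum()) + int(gt.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int((pred & gt).sum()) / denom


def _boundary_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical coordinates of boundary voxels (6-connectivity surface)."""
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    boundary = mask & ~eroded
    idx = np.argwhere(boundary)
    return idx * np.asarray(spacing, dtype=float)


def _directed_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    tree = cKDTree(dst)
    d, _ = tree.query(src, k=1)
    return d


def _surface_distances(a, b, spacing):
    a, b = _check_masks(a, b)
    if not a.any() or not b.any():
        raise ValueError("surface distances require two non-empty masks")
    pa = _boundary_points(a, spacing)
    pb = _boundary_points(b, spacing)
    return _directed_distances(pa, pb), _directed_distances(pb, pa)


def hausdorff(a: np.ndarray, b: np.ndarray, spacing, percentile: float | None = None) -> float:
    """Symmetric Hausdorff distance in mm (classical maximum).

    ``percentile`` (e.g. 95) switches to the robust percentile variant.
    """
    d_ab, d_ba = _surface_distances(a, b, spacing)
    if percentile is None:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def assd(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Average symmetric surface distance: mean of the two directed means."""
    d_ab, d_ba = _surface_distances(a, b, spacing)
    return float((d_ab.mean() + d_ba.mean()) / 2.0)


def ravd(pred: np.ndarray, gt: np.ndarray) -> float:
    """Signed relative volume difference (|pred|-|gt|)/|gt|."""
    pred, gt = _check_masks(pred, gt)
    n_gt = int(gt.sum())
    if n_gt == 0:
        raise ValueError("RAVD undefined for empty ground truth")
    return (int(pred.sum()) - n_gt) / n_gt


def segmentation_metrics(pred: np.ndarray, gt: np.ndarray, spacing) -> SegmentationMetrics:
    """All four segmentation metrics for one (pred, gt) mask pair."""
    return SegmentationMetrics(
        dice=dice(pred, gt),
        hausdorff_mm=hausdorff(pred, gt, spacing),
        assd_mm=assd(pred, gt, spacing),
        ravd=ravd(pred, gt),
    )


def pooled_recall_precision(
    detections: list[CaseDetection],
) -> tuple[float, float]:
    """Lesion-level recall and precision pooled over a cohort.

    Recall = Σ n_gt_hit / Σ n_annotated; precision = Σ hit candidates /
    Σ retained candidates. A zero denominator yields NaN with a warning.
    """
    if not detections:
        raise ValueError("need at least one case")
    n_hit = sum(d.n_gt_hit for d in detections)
    n_ann = sum(d.n_annotated for d in detections)
    n_hit_cand = sum(d.n_hit_candidates for d in detections)
    n_det = sum(d.n_detected for d in detections)
    if n_ann == 0:
        warnings.warn("no annotated lesions: recall undefined")
        recall = float("nan")
    else:
        recall = n_hit / n_ann
    if n_det == 0:
        warnings.warn("no retained candidates: precision undefined")
        precision = float("nan")
    else:
        precision = n_hit_cand / n_det
    return recall, precision


def component_analysis(
    lesion_maps: list[np.ndarray],
    case_isups: list[int] | None = None,
    voxel_volume_mm3: float = 1.0,
    aggressive_masks: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Connected-component size table over instance-labelled lesion maps.

    One row per lesion instance (case index, label, voxel count, volume mm³).
    When ``case_isups`` is given, a case graded aggressive (ISUP >= 2) whose
    (aggressive) lesion map is empty is reported with label 0 and
    ``empty_aggressive=True`` — mirroring a label-audit that surfaces
    aggressive cases with empty annotation masks.
    """
    rows = []
    for i, lab_map in enumerate(lesion_maps):
        target = lab_map if aggressive_masks is None else np.where(
            aggressive_masks[i], lab_map, 0
        )
        labels = [int(v) for v in np.unique(target) if v > 0]
        for lab in labels:
            n = int((target == lab).sum())
            rows.append(
                {
                    "case_index": i,
                    "label": lab,
                    "n_voxels": n,
                    "volume_mm3": n * voxel_volume_mm3,
                    "empty_aggressive": False,
                }
            )
        if case_isups is not None and case_isups[i] >= 2 and not labels:
            rows.append(
                {
                    "case_index": i,
                    "label": 0,
                    "n_voxels": 0,
                    "volume_mm3": 0.0,
                    "empty_aggressive": True,
                }
            )
    return pd.DataFrame(
        rows, columns=["case_index", "label", "n_voxels", "volume_mm3", "empty_aggressive"]
    )


def stratify_by_size(
    dice_scores: "np.ndarray | list[float]",
    lesion_volumes: "np.ndarray | list[float]",
) -> pd.DataFrame:
    """Median split of per-case Dice by lesion volume.

    Cases with volume <= median go to the "below" group (documented tie
    rule), the rest to "above". Returns one row per group with n, mean and
    median Dice.
    """
    d = np.asarray(dice_scores, dtype=float)
    v = np.asarray(lesion_volumes, dtype=float)
    if d.shape != v.shape or d.size < 2:
        raise ValueError("need matched Dice/volume arrays with >= 2 cases")
    med = float(np.median(v))
    group = np.where(v <= med, "below", "above")
    rows = []
    for g in ("below", "above"):
        sel = d[group == g]
        rows.append(
            {
                "group": g,
                "n": int(sel.size),
                "dice_mean": float(sel.mean()) if sel.size else float("nan"),
                "dice_median": float(np.median(sel)) if sel.size else float("nan"),
                "median_volume_mm3": med,
            }
        )
    return pd.DataFrame(rows)


def cohort_table(metadata: pd.DataFrame) -> CohortTable:
    """Cohort stratification table from per-case metadata.

    ``metadata`` needs columns ``case_id, isup, cohort, split, scanner``.
    Counts and proportions (count/total within cohort x split, rounded
    half-even to 2 decimals) per ISUP grade, plus per-scanner counts.
    """
    required = {"case_id", "isup", "cohort", "split", "scanner"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if not metadata["isup"].isin(range(6)).all():
        bad = sorted(set(metadata["isup"]) - set(range(6)))
        raise ValueError(f"unknown ISUP grades: {bad}")

    rows = []
    for (cohort, split), grp in metadata.groupby(["cohort", "split"], sort=True):
        total = len(grp)
        counts = grp["isup"].value_counts()
        for isup in range(6):
            n = int(counts.get(isup, 0))
            rows.append(
                {
                    "cohort": cohort,
                    "split": split,
                    "isup": isup,
                    "count": n,
                    "proportion": round_report(n / total),
                }
            )
    by_isup = pd.DataFrame(rows)
    by_scanner = (
        metadata.groupby(["cohort", "scanner"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return CohortTable(by_isup=by_isup, by_scanner=by_scanner)
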