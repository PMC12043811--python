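"""Case/cohort I/O and the end-to-end reproducible pipeline.

On-disk cohort layout (all volumes NIfTI, axis order (x, y, z), affine =
diag(spacing) plus origin translation)::

    <out>/
      cohort.json               # seed, n_cases, config hash
      radiologist.csv           # case_id, recommend_biopsy
      <case_id>/
        t2w.nii.gz dwi.nii.gz adc.nii.gz
        gland.nii.gz            # uint8 binary
        lesions.nii.gz          # integer instance labels
        prob.nii.gz             # detector probability map (optional)
        meta.json               # per-instance ISUP, case ISUP, tags

Every report written by :func:`run_pipeline` embeds the run seed and a
SHA-256 hash of the configuration, and the whole run is a deterministic
function of the configuration, so reports are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .candidates import CaseDetection, DetectionConfig, run_detection
from .errors import CaseIOError
from .metrics import component_analysis, dice, pooled_recall_precision, segmentation_metrics
from .phantom import (
    Cohort,
    OperatingCharacteristics,
    PhantomConfig,
    RadiologistModel,
    StudyCase,
    make_cohort,
)
from .preprocess import ImageVolume, build_stack
from .triage import TriageSummary, simulate_protocol

__all__ = [
    "RunConfig",
    "read_case",
    "write_case",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
]

_VOLUME_FILES = ("t2w", "dwi", "adc", "gland", "lesions")


def _affine(vol: ImageVolume) -> np.ndarray:
    aff = np.diag(list(vol.spacing) + [1.0])
    aff[:3, 3] = vol.origin
    return aff


def _save_nifti(vol: ImageVolume, path: Path, dtype=None) -> None:
    data = vol.values if dtype is None else vol.values.astype(dtype)
    nib.save(nib.Nifti1Image(data, _affine(vol)), str(path))


def _load_nifti(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return ImageVolume(np.asarray(img.dataobj), spacing, origin)


def write_case(case: StudyCase, case_dir: "str | Path", prob_map: ImageVolume | None = None) -> None:
    """Serialize one case (volumes + masks + metadata sidecar)."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    _save_nifti(case.t2w, case_dir / "t2w.nii.gz", np.float32)
    _save_nifti(case.dwi, case_dir / "dwi.nii.gz", np.float32)
    _save_nifti(case.adc, case_dir / "adc.nii.gz", np.float32)
    _save_nifti(case.gland, case_dir / "gland.nii.gz", np.uint8)
    _save_nifti(case.lesions, case_dir / "lesions.nii.gz", np.int16)
    if prob_map is not None:
        _save_nifti(prob_map, case_dir / "prob.nii.gz", np.float32)
    meta = {
        "case_id": case.case_id,
        "lesion_isup": {str(k): int(v) for k, v in sorted(case.lesion_isup.items())},
        "case_isup": case.case_isup,
        "cohort_tag": case.cohort_tag,
        "scanner_tag": case.scanner_tag,
    }
    (case_dir / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_case(case_dir: "str | Path") -> tuple[StudyCase, ImageVolume | None]:
    """Load a case directory; returns (case, probability map or None)."""
    case_dir = Path(case_dir)
    vols = {}
    for name in _VOLUME_FILES:
        path = case_dir / f"{name}.nii.gz"
        if not path.exists():
            raise CaseIOError(f"missing mandatory file {path.name} in {case_dir}")
        vols[name] = _load_nifti(path)

    meta_path = case_dir / "meta.json"
    if not meta_path.exists():
        raise CaseIOError(f"missing meta.json in {case_dir}")
    meta = json.loads(meta_path.read_text())

    lesions = vols["lesions"]
    if not np.issubdtype(lesions.values.dtype, np.integer):
        if not np.all(lesions.values == np.round(lesions.values)):
            raise CaseIOError("lesion instance map must hold integer labels")
        lesions = lesions.with_values(lesions.values.astype(np.int16))
        vols["lesions"] = lesions
    lesion_isup = {int(k): int(v) for k, v in meta.get("lesion_isup", {}).items()}
    for lab, isup in lesion_isup.items():
        if not 0 <= isup <= 5:
            raise CaseIOError(f"ISUP grade {isup} for instance {lab} outside 0..5")
    file_labels = {int(v) for v in np.unique(lesions.values) if v > 0}
    if file_labels - set(lesion_isup):
        raise CaseIOError(
            f"instances {sorted(file_labels - set(lesion_isup))} lack an ISUP grade"
        )
    for name in ("gland", "lesions"):
        if not vols[name].same_grid(vols["t2w"]):
            raise CaseIOError(f"{name} mask must share the T2W grid")

    prob_path = case_dir / "prob.nii.gz"
    prob = _load_nifti(prob_path) if prob_path.exists() else None
    case = StudyCase(
        case_id=meta.get("case_id", case_dir.name),
        t2w=vols["t2w"],
        dwi=vols["dwi"],
        adc=vols["adc"],
        gland=vols["gland"].with_values(vols["gland"].values.astype(np.uint8)),
        lesions=lesions,
        lesion_isup=lesion_isup,
        cohort_tag=meta.get("cohort_tag", "unknown"),
        scanner_tag=meta.get("scanner_tag", "unknown"),
    )
    return case, prob


def write_cohort(cohort: Cohort, out_dir: "str | Path") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for case, prob in zip(cohort.cases, cohort.prob_maps):
        write_case(case, out_dir / case.case_id, prob)
    rad = pd.DataFrame(
        {
            "case_id": [c.case_id for c in cohort.cases],
            "recommend_biopsy": [bool(cohort.radiologist[c.case_id]) for c in cohort.cases],
        }
    )
    rad.to_csv(out_dir / "radiologist.csv", index=False)
    (out_dir / "cohort.json").write_text(
        json.dumps({"seed": cohort.seed, "n_cases": len(cohort)}, indent=2)
    )


def read_cohort(in_dir: "str | Path") -> Cohort:
    in_dir = Path(in_dir)
    rad_path = in_dir / "radiologist.csv"
    if not rad_path.exists():
        raise CaseIOError(f"missing radiologist.csv in {in_dir}")
    rad_df = pd.read_csv(rad_path)
    reads = dict(zip(rad_df["case_id"], rad_df["recommend_biopsy"].astype(bool)))
    meta = {}
    cohort_json = in_dir / "cohort.json"
    if cohort_json.exists():
        meta = json.loads(cohort_json.read_text())
    cases, probs = [], []
    for case_dir in sorted(p for p in in_dir.iterdir() if p.is_dir()):
        case, prob = read_case(case_dir)
        cases.append(case)
        probs.append(prob)
    return Cohort(cases=cases, prob_maps=probs, radiologist=reads, seed=int(meta.get("seed", 0)))


class RunConfig(BaseModel):
    """Full configuration of a synthetic end-to-end run."""

    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    detector: OperatingCharacteristics = Field(default_factory=OperatingCharacteristics)
    radiologist: RadiologistModel = Field(default_factory=RadiologistModel)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    n_cases: int = Field(default=50, ge=1)
    seed: int = 0
    decimals: int = 2
    preprocess_stacks: bool = True  # build normalized bpMRI stacks per case

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stamp(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df.insert(0, "config_hash", cfg.config_hash())
    df.insert(1, "seed", cfg.seed)
    return df


def run_pipeline(config: RunConfig, out_dir: "str | Path", cohort: Cohort | None = None) -> dict:
    """Phantom → preprocess → detection → metrics → triage, with reports.

    Writes ``detection.csv``, ``metrics.csv``, ``triage_records.csv``,
    ``triage_summary.json``, ``component_sizes.csv``, ``run_manifest.json``
    and ``run.log`` into ``out_dir``; every table carries the config hash and
    seed. Pass a pre-generated (or loaded) ``cohort`` to skip generation.
    Returns the in-memory results (cohort, detections, summary, tables).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config_hash={config.config_hash()} seed={config.seed}"]

    if cohort is None:
        cohort = make_cohort(
            config.phantom, config.detector, config.radiologist, config.n_cases, config.seed
        )
        log.append(f"generate: {len(cohort)} cases")
    else:
        log.append(f"load: {len(cohort)} cases")

    if config.preprocess_stacks:
        for case in cohort.cases:
            build_stack(case.t2w, case.dwi, case.adc)
        log.append("preprocess: normalized bpMRI stacks built")

    detections: list[CaseDetection] = []
    metric_rows = []
    for case, prob in zip(cohort.cases, cohort.prob_maps):
        if prob is None:
            raise CaseIOError(f"case {case.case_id} has no probability map")
        det = run_detection(case, prob, config.detection)
        detections.append(det)
        gt = case.aggressive_mask()
        row = {
            "case_id": case.case_id,
            "case_isup": case.case_isup,
            "n_annotated": det.n_annotated,
            "n_detected": det.n_detected,
            "n_gt_hit": det.n_gt_hit,
            "case_probability": det.case_probability,
            "dice": dice(det.pred_mask, gt) if (det.pred_mask.any() or gt.any()) else float("nan"),
        }
        if det.pred_mask.any() and gt.any():
            seg = segmentation_metrics(det.pred_mask, gt, case.lesions.spacing)
            row.update(hausdorff_mm=seg.hausdorff_mm, assd_mm=seg.assd_mm, ravd=seg.ravd)
        else:
            row.update(hausdorff_mm=float("nan"), assd_mm=float("nan"), ravd=float("nan"))
        metric_rows.append(row)
    log.append(f"detect: {len(detections)} cases evaluated")

    recall, precision = pooled_recall_precision(detections)
    det_df = pd.DataFrame(
        [
            {
                "case_id": d.case_id,
                "n_annotated": d.n_annotated,
                "n_detected": d.n_detected,
                "n_gt_hit": d.n_gt_hit,
                "case_probability": d.case_probability,
            }
            for d in detections
        ]
    )
    metrics_df = pd.DataFrame(metric_rows)

    truths = {c.case_id: c.is_aggressive for c in cohort.cases}
    summary = simulate_protocol(detections, cohort.radiologist, truths, decimals=config.decimals)
    log.append(
        "triage: "
        f"{summary.biopsies_radiologist} radiologist biopsies -> "
        f"{summary.biopsies_hybrid} hybrid; "
        f"{summary.avoided_unnecessary} unnecessary avoided, "
        f"{summary.dangerous_avoidances} dangerous avoidances"
    )

    sizes = component_analysis(
        [c.lesions.values for c in cohort.cases],
        case_isups=[c.case_isup for c in cohort.cases],
        voxel_volume_mm3=cohort.cases[0].lesions.voxel_volume_mm3,
        aggressive_masks=[c.aggressive_mask() for c in cohort.cases],
    )

    _stamp(det_df, config).to_csv(out_dir / "detection.csv", index=False)
    _stamp(metrics_df, config).to_csv(out_dir / "metrics.csv", index=False)
    _stamp(sizes, config).to_csv(out_dir / "component_sizes.csv", index=False)
    rec_df = pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "n_annotated": r.n_annotated,
                "n_detected": r.n_detected,
                "category": r.category.value,
                "radiologist": r.radiologist,
                "cad": r.cad,
                "hybrid_biopsy": r.hybrid_biopsy,
                "truth_aggressive": r.truth_aggressive,
            }
            for r in summary.records
        ]
    )
    _stamp(rec_df, config).to_csv(out_dir / "triage_records.csv", index=False)

    summary_json = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_cases": summary.n_cases,
        "pooled_recall": recall,
        "pooled_precision": precision,
        "category_counts": {k.value: v for k, v in summary.category_counts.items()},
        "category_pct": {k.value: v for k, v in summary.category_pct.items()},
        "biopsies_radiologist": summary.biopsies_radiologist,
        "biopsies_hybrid": summary.biopsies_hybrid,
        "avoided_unnecessary": summary.avoided_unnecessary,
        "avoided_unnecessary_pct_of_cohort": summary.avoided_unnecessary_pct_of_cohort,
        "avoided_unnecessary_pct_of_negatives": summary.avoided_unnecessary_pct_of_negatives,
        "dangerous_avoidances": summary.dangerous_avoidances,
        "unnecessary_biopsies": summary.unnecessary_biopsies,
        "unnecessary_biopsies_pct_of_cohort": summary.unnecessary_biopsies_pct_of_cohort,
        "unnecessary_biopsies_pct_of_negatives": summary.unnecessary_biopsies_pct_of_negatives,
        "count_matrix": summary.count_matrix.values.tolist(),
    }
    (out_dir / "triage_summary.json").write_text(json.dumps(summary_json, indent=2, sort_keys=True))
    (out_dir / "run_manifest.json").write_text(
        json.dumps(
            {"config_hash": config.config_hash(), "seed": config.seed,
             "config": config.model_dump(mode="json")},
            indent=2,
            sort_keys=True,
        )
    )
    (out_dir / "run.log").write_text("\n".join(log) + "\n")

    return {
        "cohort": cohort,
        "detections": detections,
        "recall": recall,
        "precision": precision,
        "summary": summary,
        "detection_table": det_df,
        "metrics_table": metrics_df,
        "component_sizes": sizes,
    }
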