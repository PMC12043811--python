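# pca-triage

Lesion-level evaluation and biopsy-triage simulation for aggressive
prostate-cancer (csPCa, ISUP grade group ≥ 2) detection on biparametric MRI.

Deep-learning detectors for csPCa output voxelwise probability maps. Turning
those maps into a clinically meaningful statement — *does this patient need a
biopsy?* — requires a chain of well-defined post-processing and evaluation
steps that are easy to get subtly wrong. This package implements that chain
as a tested, reusable library:

* **Preprocessing** — DWI and ADC volumes are resampled onto the T2W grid;
  T2W/DWI are Z-scored, ADC is clipped to its 0.5/99.5 percentiles then
  Z-scored.
* **Candidate extraction** — the probability map is thresholded at 10%,
  connected components become lesion candidates with confidence = max
  probability; candidates below 10% confidence, or with less than 10% of
  their volume inside the prostate gland, are discarded.
* **Lesion matching** — retained candidates are assigned one-to-one to the
  aggressive ground-truth lesions by maximising total voxel overlap (linear
  sum assignment); a candidate counts as a hit only if it covers ≥ 10% of
  its *assigned* lesion.
* **Metrics** — Dice, Hausdorff distance, average symmetric surface
  distance, relative volume difference; pooled lesion-level recall
  `R = Σ hits / Σ annotated` and precision `P = Σ hit candidates / Σ
  retained candidates`; cohort stratification tables.
* **Triage** — each case's (annotated, detected) lesion-count pair falls in
  one of six categories (correct + avoided biopsy, correct, overestimate,
  overestimate + unnecessary biopsy, underestimate, dangerous
  underestimate), and a hybrid protocol performs a biopsy iff **both** a
  radiologist and the CAD recommend one — so the CAD can only remove
  unnecessary biopsies, never add them.
* **Calibration math** — the calibrated segmentation loss
  `½·(Dice + CE(smoothed labels, α = 0.2)) + margin hinge (m = 10)` and the
  polynomial LR schedule `lr·(1 − epoch/epoch_max)^0.9`, as stand-alone
  unit-testable functions.
* **Phantoms** — a synthetic-cohort generator (ellipsoidal gland, 0–4
  deformed-sphere lesions with log-normal sizes and ISUP grades, detector
  blobs with configurable sensitivity/confidence/false-positive rates,
  Bernoulli radiologist reads) so every stage is testable end to end with
  known ground truth.

Intended users: researchers evaluating csPCa detection models and anyone who
wants a reference implementation of lesion-level candidate selection and
biopsy-decision simulation that runs without GPUs or private data.

## Worked example

```python
from pca_triage.harness import RunConfig, run_pipeline

cfg = RunConfig(n_cases=50, seed=7)
res = run_pipeline(cfg, "out/")
print(round(res["recall"], 2), round(res["precision"], 2))
s = res["summary"]
print(s.biopsies_radiologist, "->", s.biopsies_hybrid,
      "| avoided:", s.avoided_unnecessary,
      "| dangerous:", s.dangerous_avoidances)
```

prints

```
0.93 0.41
35 -> 23 | avoided: 12 | dangerous: 0
```

Read: at the default detector operating point (85% per-lesion sensitivity,
with intra- and extra-prostatic false positives), the pipeline recovered 93%
of aggressive lesions with 41% lesion-level precision; of 35
radiologist-recommended biopsies, the hybrid protocol performed 23, avoiding
12 unnecessary ones (24% of the cohort) and no necessary one. The run
directory contains `detection.csv`, `metrics.csv`, `triage_records.csv`,
`triage_summary.json` and `component_sizes.csv`, each stamped with the seed
and a configuration hash; identical configurations reproduce the reports
byte for byte.

The same flow is available from the shell:

```bash
pca-triage run-all --n 50 --seed 7 --out out/
pca-triage generate --n 100 --seed 3 --out cohort/
pca-triage detect-eval --cohort cohort/ --out results/
pca-triage triage --cohort cohort/ --detections results/detection.csv --out triage/
```

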