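# Methods

## Problem setting

The package evaluates computer-aided detection (CAD) of clinically
significant prostate cancer (csPCa) on biparametric MRI. "Aggressive" is
defined histologically: a lesion is aggressive when its ISUP grade group is
≥ 2; a case is aggressive when its maximum lesion grade (the index-lesion
convention) is ≥ 2, and 0 denotes a confirmed or assumed negative. The unit
of analysis is a case consisting of T2W/DWI/ADC volumes, a whole-gland mask,
an integer instance-labelled lesion mask with per-instance grades, and a
detector probability map on the T2W grid.

## Preprocessing

DWI and ADC are resampled to the space and size of the T2W volume
(trilinear for images, nearest-neighbour for masks, which preserves label
sets; out-of-field samples clamp to the edge). T2W and DWI are Z-scored
(subtract mean, divide population SD); ADC is clipped to its own 0.5/99.5
percentiles and then Z-scored with the clipped volume's statistics.
Choices the definition leaves open, and how they are resolved here:

* percentile = linear-interpolation quantile (numpy's default);
* statistics over **all** voxels, not gland-restricted and not per-slice; a
  `mask` argument allows gland-restricted or background-excluding variants;
* a constant volume is a degenerate input and raises rather than returning
  zeros.

Z-scoring is invariant to positive affine rescaling of the input, and
resampling a volume onto its own grid is the exact identity (special-cased,
so no interpolation noise is introduced).

## Candidate selection and lesion matching

Given a probability map in [0, 1]:

1. voxels with probability ≥ 0.10 form the support ("soft blobs");
2. connected components of the support (26-neighbourhood by default) become
   candidates; candidate confidence is the maximum probability inside it,
   volume is voxel count × voxel volume;
3. candidates with confidence < 0.10 are dropped;
4. candidates with gland-overlap fraction < 0.10 are dropped as
   extra-prostatic; the fraction's denominator is the **candidate's own
   volume** — the rule describes how much of the finding lies inside the
   gland while tolerating extracapsular extension;
5. retained candidates are assigned one-to-one to aggressive ground-truth
   lesions by maximising total overlapping voxels (Hungarian / linear sum
   assignment); pairs with zero overlap are never matched;
6. a matched candidate is a hit iff its overlap with its assigned lesion is
   ≥ 0.10 of that **lesion's** volume. Covering some other lesion in the
   same case does not make a candidate a hit. The alternative
   candidate-volume denominator is config-selectable
   (`DetectionConfig.hit_denominator`).

All four thresholds default to 0.10 and all comparisons are inclusive (≥):
since voxels *below* 10% are clipped, a value exactly at 10% survives; the
same convention is applied to the other three rules for consistency.

Per case the pipeline reports: `n_annotated` (aggressive ground-truth
lesions), `n_detected` (retained candidates — the CAD's lesion-count claim,
deliberately not the hit count so over-detection is expressible),
`n_gt_hit`, and the case probability (max retained confidence, 0 if none).
ISUP-1 lesions are excluded from ground truth entirely by default; a config
flag lets them participate in assignment as distractors without ever
counting as annotated. An aggressive case with an empty lesion mask is
valid input and is flagged in reports, not rejected — such label defects
occur in real repositories and an audit function (`component_analysis`)
surfaces them.

## Metrics

* Dice = 2|A∩B|/(|A|+|B|); undefined (NaN, excluded from averages) when
  both masks are empty. In cohort reports Dice is computed on the union of
  retained candidates against the aggressive ground-truth mask — i.e. on
  the output of candidate selection, not the raw thresholded map.
* Surfaces are boundary voxels: mask voxels with a background neighbour
  under 6-connectivity. Distances are Euclidean between boundary-voxel
  centres with physical spacing applied. HD is the classical maximum of the
  two directed maxima (a percentile option provides HD95); ASSD is the
  average of the two directed means. These match the conventions of the
  standard medical evaluation libraries and are verified in tests against
  an all-pairs brute-force oracle at 1e-9.
* RAVD = (|pred| − |gt|)/|gt|, signed; take the absolute value where a
  magnitude is wanted.
* Pooled lesion-level recall and precision are ratio-of-sums over a cohort
  (equivalently, annotation-count-weighted means of per-case values).
  Report views round half-even to 2 decimals, matching table precision.
* The size stratification splits cases at the median lesion volume; ties
  (volume = median) go to the "below" group.

## Triage and the hybrid protocol

The (n_annotated, n_detected) pair maps to exactly one of six categories:
(0,0) correct + avoided biopsy; (0,>0) overestimate + unnecessary biopsy;
(n,n) correct; (n,>n) overestimate; (n≥2, 1..n−1) underestimate; (n≥2, 0)
dangerous underestimate. The literal category list does not cover (1,0); a
missed solitary lesion avoids a *necessary* biopsy, so it is classified as
a dangerous underestimate by default (`strict_categories=True` restores the
literal partition and reports (1,0) separately).

The CAD recommends a biopsy iff it retained at least one candidate —
equivalent to the case probability clearing the confidence threshold. The
hybrid protocol performs a biopsy iff both the radiologist and the CAD
recommend it, so the hybrid biopsy set is always a subset of the
radiologist's; the CAD can only remove biopsies. Cohort summaries count
avoided unnecessary biopsies (radiologist yes, CAD no, truth negative) and
dangerous avoidances (radiologist yes, CAD no, truth positive).

Published analyses of this design report the avoided-biopsy share against
denominators that cannot be reconciled from their text (whole cohort vs the
negative subset); the summary therefore carries **both** percentage
conventions explicitly (`*_pct_of_cohort`, `*_pct_of_negatives`).

## Calibrated loss and LR schedule

`calibrated_loss = w_d·softDice + w_ce·CE(softmax(logits), smoothed labels)
+ margin penalty`, defaults w_d = w_ce = ½, α = 0.2, m = 10. Label
smoothing: y′ = y(1−α) + α/K. Soft Dice: 1 − (2Σpg+ε)/(Σp+Σg+ε) over
foreground channels, ε = 1e-5 (the source formulation specifies neither ε
nor channel handling; these are this package's choices). The margin
penalty is the hinge on per-voxel logit gaps, mean over voxels and classes
of max(0, (max-logit − logit_k) − m) — the max-gap form from the
margin-based calibration literature; the exact published formulation is not
spelled out, so the hinge is kept pluggable. With α = 0 and m → ∞ the loss
reduces exactly to the plain average of Dice and cross-entropy (tested to
1e-6 against an independent loop re-implementation). The LR schedule is
lr·(1 − epoch/epoch_max)^0.9 with base 0.001. No training loop is provided;
these functions document and test the math only.

## Synthetic phantoms

The generator emulates the *structure* of a csPCa cohort, not its physics:

* **Gland**: an ellipsoid at the grid centre, default semi-axes
  (24, 20, 17) mm jittered ±10% per case — a typical whole-gland envelope.
  Grid 72×72×24 voxels at (1.5, 1.5, 3.0) mm, matching the anisotropic
  in-plane/through-plane resolution of prostate MRI.
* **Lesions**: 0–4 per case (default probabilities 0.40/0.30/0.20/0.07/0.03);
  radii log-normal (right-skewed, as observed lesion-size distributions
  are), with a larger-lesion preset (`pnet_like`, median 6 mm) and a
  smaller-lesion preset (`picai_like`, median 4.5 mm). No published
  quantitative size parameters exist for the cohorts these presets mimic,
  so the values are free configuration chosen once as plausible, not
  calibrated. Each lesion is a sphere deformed by a smoothed noise field,
  placed so it lies ≥ 90% (in practice entirely) inside the gland, with a
  minimum inter-lesion gap (8 mm) so distinct lesions produce distinct
  supra-threshold detector blobs; placement retries shrink the radius
  before ever relaxing the gap, so configured lesion counts are always
  delivered. Per-lesion ISUP grades are sampled independently (default mix
  0.52/0.22/0.14/0.07/0.02/0.03 over grades 0–5, the published
  training-cohort mix); the case grade is the maximum.
* **Intensities**: constant tissue classes (background/gland/lesion) with
  sequence-appropriate contrast signs (lesions T2W- and ADC-hypointense,
  DWI-hyperintense) plus Gaussian noise. A `dwi_coarse_factor` puts DWI/ADC
  on a coarser in-plane grid to exercise resampling.
* **Detector**: each aggressive lesion is detected independently with
  probability `sensitivity`; a detected lesion's blob is its own voxel mask
  blurred (σ = 1.5 mm) and rescaled to a peak confidence drawn from a Beta
  distribution on [0.2, 1]. Building the blob from the lesion's actual
  support guarantees the hit rule is satisfiable whenever the confidence
  clears the extraction threshold, so pipeline recall measures the
  configured sensitivity and nothing else. False positives are blurred
  spheres at Poisson counts, either inside the gland or at a clearance
  distance that keeps their supra-threshold support fully extra-prostatic
  (these must be removed by the gland filter, 100% of the time). Optionally
  ISUP-1 lesions emit low-confidence blobs (off by default, mirroring a
  detector trained on aggressive-only positives).
* **Radiologist**: Bernoulli reads with configurable
  sensitivity/specificity (defaults 0.91/0.35, the high-sensitivity
  low-specificity regime typical of PI-RADS-driven referral).
* **Randomness**: every draw comes from a `SeedSequence([component_seed,
  stream_tag, call_seed])` stream; `make_cohort` rewires all component
  seeds to one master seed, making a cohort a pure function of
  (configuration, n, seed), bit-identical across runs and platforms.

What the phantoms do **not** model: MR physics and artefacts, anatomical
zonal structure, irregular or infiltrative lesion shapes, annotation
variability, and correlations between lesion size, grade and detectability.
Passing tests therefore demonstrate that the *analysis chain* is correct
and recovers known operating characteristics — not that any detector
performs well on real data.

## Problem sizes and numerical choices

Cohort-level tests use 40–300 cases on the 72×72×24 grid; recovery checks
compare empirical rates to configured ones within 3 binomial SDs of the
relevant sample size. Matching is verified against exhaustive-permutation
optima for up to 6×6 instances; surface metrics against O(n²) brute force
on small random masks at 1e-9. Report rounding is half-even at 2 decimals
(1 for the prospective-style percentage). Degenerate inputs have explicit
behaviour: constant volumes raise; both-empty Dice is NaN and excluded;
empty ground truth makes RAVD and surface distances errors; an empty gland
mask demotes every candidate with a warning.

## Known limitations

* The hybrid-protocol simulation assumes the radiologist and CAD err
  independently; automation bias and reader-interaction effects are out of
  scope.
* `n_detected` counts retained candidates, so two candidates hitting the
  same lesion register as over-detection; with the phantom's separation
  guarantees this is rare but it is the intended semantics.
* Phantom lesions are near-convex blobs; candidate-splitting behaviour on
  ring- or sheet-shaped predictions is untested against real detectors.
* The classical Hausdorff distance is noise-sensitive; prefer the HD95
  option for robust comparisons.
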