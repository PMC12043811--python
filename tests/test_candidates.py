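"""Candidate extraction/filtering/matching against brute-force oracles."""

import itertools

import numpy as np
import pytest

from pca_triage import (
    DetectionConfig,
    ImageVolume,
    LesionCandidate,
    assign_candidates,
    extract_candidates,
    filter_confidence,
    filter_gland_overlap,
    make_case,
    make_probability_map,
    run_detection,
    score_hits,
    threshold_map,
)
from pca_triage.candidates import BELOW_CONFIDENCE, EXTRA_PROSTATIC


def _pm(values, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(values, dtype=float), spacing)


def _flood_fill_components(support):
    """Independent BFS flood fill under 26-connectivity."""
    visited = np.zeros_like(support, dtype=bool)
    comps = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(support)):
        if visited[start]:
            continue
        stack, comp = [start], set()
        visited[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for off in offsets:
                w = tuple(a + b for a, b in zip(v, off))
                if all(0 <= wi < si for wi, si in zip(w, support.shape)):
                    if support[w] and not visited[w]:
                        visited[w] = True
                        stack.append(w)
        comps.append(frozenset(comp))
    return set(comps)


class TestThreshold:
    def test_zero_map_empty_support(self):
        assert not threshold_map(_pm(np.zeros((4, 4, 4))), 0.1).any()

    def test_boundary_value_included(self):
        vals = np.zeros((3, 3, 3))
        vals[1, 1, 1] = 0.10
        assert threshold_map(_pm(vals), 0.10)[1, 1, 1]

    def test_matches_voxelwise_scan(self, rng):
        vals = rng.random((6, 6, 6))
        support = threshold_map(_pm(vals), 0.4)
        expected = np.array(
            [v >= 0.4 for v in vals.ravel()], dtype=bool
        ).reshape(vals.shape)
        assert np.array_equal(support, expected)

    @pytest.mark.parametrize("t", [0.0, 1.0, -0.5, 1.5])
    def test_invalid_threshold(self, t):
        with pytest.raises(ValueError):
            threshold_map(_pm(np.zeros((2, 2, 2))), t)


class TestExtract:
    def test_two_separated_blobs(self):
        vals = np.zeros((8, 8, 8))
        vals[1:3, 1:3, 1:3] = 0.5
        vals[5:7, 5:7, 5:7] = 0.7
        pm = _pm(vals)
        cands = extract_candidates(threshold_map(pm, 0.1), pm)
        assert len(cands) == 2

    def test_confidence_is_max_probability(self):
        vals = np.zeros((5, 5, 5))
        vals[2, 1:4, 2] = [0.2, 0.5, 0.3]
        pm = _pm(vals)
        (cand,) = extract_candidates(threshold_map(pm, 0.1), pm)
        assert cand.confidence == pytest.approx(0.5)
        assert cand.volume_mm3 == pytest.approx(3.0)

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            support = rng.random((7, 7, 5)) > 0.7
            pm = _pm(rng.random((7, 7, 5)))
            cands = extract_candidates(support, pm)
            got = {
                frozenset(map(tuple, np.array(np.unravel_index(c.indices, support.shape)).T))
                for c in cands
            }
            assert got == _flood_fill_components(support)


class TestFilters:
    def _cands(self, confidences):
        return [
            LesionCandidate(i, np.array([i]), c, 1.0) for i, c in enumerate(confidences)
        ]

    def test_confidence_partition(self):
        kept, dropped = filter_confidence(self._cands([0.08, 0.5]), 0.10)
        assert [c.confidence for c in kept] == [0.5]
        assert dropped[0].status == BELOW_CONFIDENCE

    def test_empty_list(self):
        assert filter_confidence([], 0.1) == ([], [])

    def test_raising_threshold_monotone(self, rng):
        cands = self._cands(rng.random(50))
        sizes = [len(filter_confidence(self._cands([c.confidence for c in cands]), t)[0])
                 for t in (0.1, 0.3, 0.5, 0.8)]
        assert sizes == sorted(sizes, reverse=True)

    def test_gland_overlap_fractions(self):
        gland = np.zeros((4, 4, 4), dtype=bool)
        gland[:2] = True
        inside = LesionCandidate(1, np.flatnonzero(gland)[:8], 0.5, 8.0)
        outside_idx = np.flatnonzero(~gland)[:8]
        outside = LesionCandidate(2, outside_idx, 0.5, 8.0)
        kept, dropped = filter_gland_overlap([inside, outside], gland, 0.10)
        assert kept == [inside] and inside.gland_fraction == 1.0
        assert dropped == [outside] and outside.gland_fraction == 0.0
        assert outside.status == EXTRA_PROSTATIC

    def test_exact_boundary_fraction_retained(self):
        """3 of 30 voxels inside at t=0.10 -> fraction exactly 0.10, kept."""
        gland = np.zeros((30, 1, 1), dtype=bool)
        gland[:3] = True
        cand = LesionCandidate(1, np.arange(30), 0.5, 30.0)
        kept, _ = filter_gland_overlap([cand], gland, 0.10)
        assert cand.gland_fraction == pytest.approx(0.10)
        assert kept == [cand]

    def test_empty_gland_mask_warns_and_removes_all(self):
        cand = LesionCandidate(1, np.arange(5), 0.5, 5.0)
        with pytest.warns(UserWarning):
            kept, dropped = filter_gland_overlap([cand], np.zeros((2, 2, 2), bool), 0.1)
        assert kept == [] and len(dropped) == 1


def _random_instance(rng, n_cands, n_gt, shape=(8, 8, 4)):
    gt = np.zeros(shape, dtype=np.int16)
    size = shape[0] * shape[1] * shape[2]
    for lab in range(1, n_gt + 1):
        idx = rng.choice(size, size=rng.integers(3, 12), replace=False)
        gt.ravel()[idx] = lab
    cands = []
    for cid in range(1, n_cands + 1):
        idx = rng.choice(size, size=rng.integers(3, 12), replace=False)
        cands.append(LesionCandidate(cid, np.sort(idx), 0.5, float(idx.size)))
    return cands, gt


def _brute_force_best(cands, gt, labels):
    if not cands or not labels:
        return 0
    overlap = np.array(
        [[(gt.ravel()[c.indices] == lab).sum() for lab in labels] for c in cands]
    )
    n_c, n_g = overlap.shape
    best = 0
    k = min(n_c, n_g)
    for rows in itertools.permutations(range(n_c), k):
        for cols in itertools.permutations(range(n_g), k):
            best = max(best, sum(overlap[r, c] for r, c in zip(rows, cols)))
    return best


class TestAssignment:
    def test_single_pair_matched(self, rng):
        gt = np.zeros((5, 5, 5), dtype=np.int16)
        gt[1:3, 1:3, 1:3] = 1
        cand = LesionCandidate(1, np.flatnonzero(gt.ravel() == 1)[:4], 0.6, 4.0)
        matching = assign_candidates([cand], gt)
        assert matching == {1: 1} and cand.matched_gt == 1

    def test_two_by_two_overlap_matrix(self):
        """Overlap [[5,1],[2,4]] -> diagonal matching, total 9."""
        gt = np.zeros((20, 1, 1), dtype=np.int16)
        gt[0:6, 0, 0] = 1   # lesion 1: voxels 0..5
        gt[10:15, 0, 0] = 2  # lesion 2: voxels 10..14
        c1 = LesionCandidate(1, np.array([0, 1, 2, 3, 4, 10]), 0.5, 6.0)
        c2 = LesionCandidate(2, np.array([4, 5, 10, 11, 12, 13]), 0.5, 6.0)
        matching = assign_candidates([c1, c2], gt)
        assert matching == {1: 1, 2: 2}

    def test_zero_overlap_never_matched(self):
        gt = np.zeros((4, 4, 4), dtype=np.int16)
        gt[0, 0, 0] = 1
        cand = LesionCandidate(1, np.array([30, 31]), 0.5, 2.0)
        assert assign_candidates([cand], gt) == {}
        assert cand.matched_gt is None

    def test_matches_permutation_oracle(self, rng):
        for _ in range(60):
            n_c = int(rng.integers(0, 6))
            n_g = int(rng.integers(0, 6))
            cands, gt = _random_instance(rng, n_c, n_g)
            labels = sorted(int(v) for v in np.unique(gt) if v > 0)
            matching = assign_candidates(cands, gt, labels)
            total = sum(
                (gt.ravel()[c.indices] == c.matched_gt).sum()
                for c in cands
                if c.matched_gt is not None
            )
            assert total == _brute_force_best(cands, gt, labels)


class TestHitScoring:
    def test_full_coverage_is_hit(self):
        gt = np.zeros((4, 4, 4), dtype=np.int16)
        gt[1:3, 1:3, 1] = 1
        cand = LesionCandidate(1, np.flatnonzero(gt.ravel() == 1), 0.5, 4.0)
        cand.matched_gt = 1
        detected = score_hits([cand], gt, 0.10)
        assert detected == {1} and cand.hit_fraction == 1.0

    def test_insufficient_overlap_misses(self):
        """Covering 2 of 40 lesion voxels (5%) is below the 10% hit rule."""
        gt = np.zeros((40, 1, 1), dtype=np.int16)
        gt[:40, 0, 0] = 1
        cand = LesionCandidate(1, np.array([0, 1]), 0.9, 2.0)
        cand.matched_gt = 1
        assert score_hits([cand], gt, 0.10) == set()
        assert cand.hit_fraction == pytest.approx(0.05)

    def test_hit_fraction_matches_count_oracle(self, rng):
        for _ in range(20):
            cands, gt = _random_instance(rng, 3, 3)
            labels = sorted(int(v) for v in np.unique(gt) if v > 0)
            assign_candidates(cands, gt, labels)
            score_hits(cands, gt, 0.10)
            for c in cands:
                if c.matched_gt is None:
                    continue
                inter = sum(
                    1 for i in c.indices if gt.ravel()[i] == c.matched_gt
                )
                assert c.hit_fraction == pytest.approx(inter / (gt == c.matched_gt).sum())

    def test_candidate_denominator_option(self):
        gt = np.zeros((40, 1, 1), dtype=np.int16)
        gt[:4, 0, 0] = 1
        cand = LesionCandidate(1, np.arange(8), 0.9, 8.0)
        cand.matched_gt = 1
        assert score_hits([cand], gt, 0.10, denominator="lesion") == {1}
        cand2 = LesionCandidate(1, np.arange(8), 0.9, 8.0)
        cand2.matched_gt = 1
        assert score_hits([cand2], gt, 0.55, denominator="candidate") == set()


class TestRunDetection:
    def test_zero_map_empty_case(self, small_config, perfect_detector):
        cfg = small_config.model_copy(
            update={"lesion_count_probs": (1.0, 0.0, 0.0, 0.0, 0.0)}
        )
        case = make_case(cfg, 0)
        pm = ImageVolume(np.zeros(case.lesions.shape), case.lesions.spacing)
        det = run_detection(case, pm)
        assert (det.n_annotated, det.n_detected, det.n_gt_hit) == (0, 0, 0)
        assert det.case_probability == 0.0

    def test_perfect_detector_hits_every_lesion(
        self, aggressive_only_config, perfect_detector
    ):
        for seed in range(10):
            case = make_case(aggressive_only_config, seed)
            pm = make_probability_map(case, perfect_detector, seed)
            det = run_detection(case, pm)
            assert det.n_gt_hit == det.n_annotated

    def test_relabeling_ground_truth_invariant(
        self, aggressive_only_config, perfect_detector
    ):
        case = make_case(aggressive_only_config, 1)
        pm = make_probability_map(case, perfect_detector, 1)
        base = run_detection(case, pm)
        # permute instance labels
        mapping = {lab: 100 + lab for lab in case.lesion_isup}
        relabeled = case.lesions.values.copy()
        for old, new in mapping.items():
            relabeled[case.lesions.values == old] = new
        case.lesions = case.lesions.with_values(relabeled)
        case.lesion_isup = {mapping[k]: v for k, v in case.lesion_isup.items()}
        redo = run_detection(case, pm)
        assert (redo.n_annotated, redo.n_detected, redo.n_gt_hit) == (
            base.n_annotated,
            base.n_detected,
            base.n_gt_hit,
        )

    def test_threshold_monotonicity(self, aggressive_only_config):
        """Raising any threshold never increases detections or hits."""
        oc = perfect = None
        from pca_triage import OperatingCharacteristics

        oc = OperatingCharacteristics(
            sensitivity=1.0, fp_rate_inside=1.0, fp_rate_outside=0.5, seed=4
        )
        cases = [make_case(aggressive_only_config, s) for s in range(5)]
        maps = [make_probability_map(c, oc, s) for s, c in enumerate(cases)]
        for name in (
            "voxel_threshold",
            "confidence_threshold",
            "gland_overlap_threshold",
            "hit_threshold",
        ):
            prev_det = prev_hit = None
            for t in (0.10, 0.35, 0.60):
                cfg = DetectionConfig(**{name: t})
                n_det = n_hit = 0
                for case, pm in zip(cases, maps):
                    det = run_detection(case, pm, cfg)
                    n_det += det.n_detected
                    n_hit += det.n_gt_hit
                if prev_det is not None:
                    assert n_det <= prev_det
                    assert n_hit <= prev_hit
                prev_det, prev_hit = n_det, n_hit

    def test_retained_candidates_satisfy_thresholds(
        self, aggressive_only_config
    ):
        from pca_triage import OperatingCharacteristics

        oc = OperatingCharacteristics(
            sensitivity=0.9, fp_rate_inside=1.0, fp_rate_outside=1.0, seed=8
        )
        cfg = DetectionConfig()
        for seed in range(5):
            case = make_case(aggressive_only_config, seed)
            pm = make_probability_map(case, oc, seed)
            det = run_detection(case, pm, cfg)
            seen = set()
            for c in det.candidates:
                assert c.confidence >= cfg.confidence_threshold
                assert c.gland_fraction >= cfg.gland_overlap_threshold
                idx = set(c.indices.tolist())
                assert not (idx & seen)  # pairwise disjoint
                seen |= idx
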