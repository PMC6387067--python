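"""Counting pipeline: segmentation, MSER detection, classification, matching."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from focirad import foci_pipeline as fp
from focirad import synthetic_data as syn
from focirad.datatypes import ConfocalStack, FocusCall, FocusCandidate, NucleusLabelMap
from focirad.pipeline_training import match_candidates_to_truth, _truth_id


def _dice(a, b):
    return 2 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b))


class TestSegmentation:
    def test_all_background_yields_empty_label_map(self):
        stack = ConfocalStack(
            {"chromatin": np.zeros((10, 32, 32))}, (0.3, 0.1, 0.1)
        )
        lm = fp.segment_nuclei(stack)
        assert lm.ids == []
        assert lm.labels.max() == 0

    def test_missing_chromatin_channel_is_an_error(self):
        stack = ConfocalStack({"gH2AX": np.zeros((4, 8, 8))}, (0.3, 0.1, 0.1))
        with pytest.raises(KeyError, match="chromatin"):
            fp.segment_nuclei(stack)

    def test_three_disjoint_nuclei_recovered_with_high_dice(self):
        rng = np.random.default_rng(0)
        stack, truth = syn.simulate_stack(0.0, 0.0, 3, rng=rng)
        lm = fp.segment_nuclei(stack)
        assert len(lm.ids) == 3
        for nid in lm.ids:
            tid = _truth_id(lm, truth, nid)
            assert _dice(lm.labels == nid, truth.nucleus_masks == tid) >= 0.9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_touching_pair_split_by_watershed(self, seed):
        rng = np.random.default_rng(seed)
        stack, truth = syn.simulate_stack(0.0, 0.0, 1, rng=rng, touching=True)
        lm = fp.segment_nuclei(stack)
        assert len(lm.ids) == 2
        # each true nucleus center is claimed by a distinct label
        labels_at_centers = set()
        for nid in (1, 2):
            zz, yy, xx = np.nonzero(truth.nucleus_masks == nid)
            labels_at_centers.add(
                int(lm.labels[int(zz.mean()), int(yy.mean()), int(xx.mean())])
            )
        assert len(labels_at_centers) == 2 and 0 not in labels_at_centers


def _single_spot_stack(snr=10.0, center=(20, 32, 32), sigma=(1.5, 2.5, 2.5)):
    """One Gaussian spot over Poisson background inside a cuboid 'nucleus'."""
    rng = np.random.default_rng(9)
    shape = (40, 64, 64)
    bg = 100.0
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]].astype(float)
    amp = snr * np.sqrt(bg)
    signal = bg + amp * np.exp(
        -0.5 * (
            ((zz - center[0]) / sigma[0]) ** 2
            + ((yy - center[1]) / sigma[1]) ** 2
            + ((xx - center[2]) / sigma[2]) ** 2
        )
    )
    img = rng.poisson(signal).astype(np.uint16)
    stack = ConfocalStack(
        {"gH2AX": img, "chromatin": np.full(shape, 10, np.uint16)}, (0.3, 0.1, 0.1)
    )
    labels = np.zeros(shape, np.int32)
    labels[2:-2, 4:-4, 4:-4] = 1
    lm = NucleusLabelMap(labels, {1: (slice(2, 38), slice(4, 60), slice(4, 60))})
    return stack, lm


class TestDetection:
    def test_uniform_nucleus_has_no_candidates(self):
        shape = (12, 40, 40)
        stack = ConfocalStack(
            {"gH2AX": np.full(shape, 55, np.uint16),
             "chromatin": np.full(shape, 10, np.uint16)},
            (0.3, 0.1, 0.1),
        )
        labels = np.ones(shape, np.int32)
        lm = NucleusLabelMap(labels, {1: (slice(0, 12), slice(0, 40), slice(0, 40))})
        assert fp.detect_candidates(stack, lm, 1, "gH2AX") == []

    def test_single_spot_found_within_one_voxel_of_oracle(self):
        stack, lm = _single_spot_stack()
        cands = fp.detect_candidates(stack, lm, 1, "gH2AX")
        # strong candidates only (the detector is high-recall by design)
        best = max(cands, key=lambda c: c.volume_voxels)
        # independent oracle: intensity-weighted centroid of the voxels above
        # half of the background-subtracted peak, from a plain threshold sweep
        img = stack.channels["gH2AX"].astype(float)
        bg = np.median(img)
        thr = bg + 0.5 * (img.max() - bg)
        zz, yy, xx = np.nonzero(img >= thr)
        w = img[zz, yy, xx] - bg
        oracle = np.array(
            [np.average(zz, weights=w), np.average(yy, weights=w), np.average(xx, weights=w)]
        )
        got = np.array(best.centroid_um) / np.array([0.3, 0.1, 0.1])
        assert np.all(np.abs(got - oracle) <= 1.0)
        # and within one voxel of the true center
        assert np.all(np.abs(got - np.array([20, 32, 32])) <= 1.0)

    def test_invalid_channel_rejected(self, small_stack, small_label_map):
        stack, _ = small_stack
        with pytest.raises(ValueError):
            fp.detect_candidates(stack, small_label_map, 1, "chromatin")

    def test_well_separated_foci_candidate_recall(self):
        cfg = syn.ScenarioConfig(baseline_rate=0.0, focus_min_separation_um=1.2)
        total = hits = 0
        for seed in range(2):
            rng = np.random.default_rng(seed)
            stack, truth = syn.simulate_stack(1.0, 60.0, 4, cfg, rng=rng)
            lm = fp.segment_nuclei(stack)
            for nid in lm.ids:
                tid = _truth_id(lm, truth, nid)
                cands = fp.detect_candidates(stack, lm, nid, "gH2AX")
                y = match_candidates_to_truth(cands, truth.foci, tid, "gH2AX")
                total += (truth.foci.nucleus_id == tid).sum()
                hits += y.sum()
        assert hits / total >= 0.95


class TestFeatures:
    def test_flat_candidate_on_flat_background_has_zero_contrast(self):
        shape = (8, 20, 20)
        stack = ConfocalStack(
            {"gH2AX": np.full(shape, 40.0), "chromatin": np.full(shape, 5.0)},
            (0.3, 0.1, 0.1),
        )
        vox = np.array([[4, 10, 10], [4, 10, 11], [4, 11, 10], [4, 11, 11]])
        cand = FocusCandidate(vox, (1.2, 1.0, 1.0), 4, 4, 40.0, 0.1, "gH2AX", 1)
        feats = fp.extract_features(cand, stack)
        names = dict(zip(fp.FEATURE_NAMES, feats))
        assert names["contrast"] == pytest.approx(0.0, abs=1e-9)
        assert names["rel_mean_intensity"] == pytest.approx(1.0)

    def test_candidate_summary_fields(self):
        shape = (8, 20, 20)
        img = np.zeros(shape)
        vox = np.array([[3, 5, 5 + i] for i in range(10)])
        img[vox[:, 0], vox[:, 1], vox[:, 2]] = 7.0
        stack = ConfocalStack(
            {"gH2AX": img, "chromatin": np.full(shape, 5.0)}, (0.3, 0.1, 0.1)
        )
        vals = img[vox[:, 0], vox[:, 1], vox[:, 2]]
        assert vals.mean() == pytest.approx(7.0)
        assert len(vox) == 10

    def test_empty_voxel_set_rejected(self):
        shape = (4, 8, 8)
        stack = ConfocalStack(
            {"gH2AX": np.zeros(shape), "chromatin": np.zeros(shape)}, (0.3, 0.1, 0.1)
        )
        cand = FocusCandidate(np.empty((0, 3), int), (0, 0, 0), 0, 0, 0.0, 0.0, "gH2AX", 1)
        with pytest.raises(ValueError):
            fp.extract_features(cand, stack)


class TestClassifier:
    def test_separable_toy_problem_held_out_accuracy(self):
        rng = np.random.default_rng(0)
        n = 400
        X0 = rng.normal(0, 1, (n, 2))
        X1 = rng.normal(4, 1, (n, 2))
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], n)
        idx = rng.permutation(2 * n)
        train, test = idx[:n], idx[n:]
        clf = fp.train_classifier(X[train], y[train])
        pred = clf.margins(X[test]) > 0
        assert (pred == y[test]).mean() >= 0.95

    def test_label_inversion_negates_the_rule(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(3, 1, (100, 3))])
        y = np.repeat([0, 1], 100)
        a = fp.train_classifier(X, y)
        b = fp.train_classifier(X, 1 - y)
        cos = np.dot(a.weights, b.weights) / (
            np.linalg.norm(a.weights) * np.linalg.norm(b.weights)
        )
        assert cos < -0.99

    def test_conflicting_duplicates_fit_near_chance(self):
        X = np.tile([[1.0, 2.0]], (40, 1))
        y = np.array([0, 1] * 20)
        clf = fp.train_classifier(X, y)
        assert 0.4 <= clf.training_accuracy <= 0.6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fp.train_classifier(np.ones((10, 2)), np.ones(10))

    def test_features_separate_true_foci_from_noise(self, classifier):
        from focirad.pipeline_training import collect_training_set
        from sklearn.metrics import roc_auc_score

        X, y = collect_training_set(np.random.default_rng(314), n_nuclei=9)
        assert roc_auc_score(y, classifier.margins(X)) >= 0.95

    def test_bias_shift_monotone_and_limits(self, classifier, small_stack, small_label_map):
        stack, _ = small_stack
        cands = fp.detect_candidates(stack, small_label_map, small_label_map.ids[0], "gH2AX")
        X = np.array([fp.extract_features(c, stack, small_label_map) for c in cands])
        sizes = []
        for bias in (-np.inf, -2.0, 0.0, 2.0, np.inf):
            calls = fp.classify(cands, X, classifier, bias)
            sizes.append(sum(c.accepted for c in calls))
        assert sizes[0] == 0
        assert sizes[-1] == len(cands)
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_classifier_json_round_trip(self, classifier):
        clone = fp.FociClassifier.from_json(classifier.to_json())
        X = np.random.default_rng(0).normal(size=(5, len(fp.FEATURE_NAMES)))
        np.testing.assert_allclose(clone.margins(X), classifier.margins(X))


def _call(z, y, x, nucleus=1, channel="gH2AX", accepted=True, vol=10):
    vox = np.array([[0, 0, 0]])
    return FocusCall(
        voxels=vox, centroid_um=(z, y, x), volume_voxels=vol, area_pixels=vol,
        mean_intensity=1.0, stability=0.1, channel=channel, nucleus_id=nucleus,
        margin=1.0, accepted=accepted,
    )


class TestMatching:
    def test_identical_lists_fully_matched(self):
        g = [_call(1, 1, 1), _call(2, 2, 2)]
        p = [_call(1, 1, 1, channel="p53BP1"), _call(2, 2, 2, channel="p53BP1")]
        # same voxel placeholder => overlap fraction 1
        calls = fp.match_colocalized(g, p)
        assert len(calls) == 2
        assert all(c.distance_um == pytest.approx(0.0) for c in calls)
        assert all(c.overlap_fraction == pytest.approx(1.0) for c in calls)

    def test_empty_side_gives_no_dsbs(self):
        assert fp.match_colocalized([], [_call(1, 1, 1)]) == []
        assert fp.match_colocalized([_call(1, 1, 1)], []) == []

    @pytest.mark.parametrize("jitter,expected", [(0.3, 5), (0.8, 0)])
    def test_jittered_pairs_within_and_beyond_threshold(self, jitter, expected):
        rng = np.random.default_rng(4)
        g, p = [], []
        for k in range(5):
            base = np.array([3.0, 2.0 + 2 * k, 2.0])
            g.append(_call(*base))
            direction = rng.normal(size=3)
            direction *= jitter / np.linalg.norm(direction)
            p.append(_call(*(base + direction), channel="p53BP1"))
        assert len(fp.match_colocalized(g, p, d_max_um=0.5)) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_matches_as_many_as_optimal_assignment(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 10, 2)
        g = [_call(*rng.uniform(0, 4, 3)) for _ in range(n)]
        p = [_call(*rng.uniform(0, 4, 3), channel="p53BP1") for _ in range(m)]
        got = fp.match_colocalized(g, p, d_max_um=0.5)
        # oracle: optimal assignment on the bipartite distance matrix
        D = np.array(
            [[np.linalg.norm(np.array(a.centroid_um) - np.array(b.centroid_um))
              for b in p] for a in g]
        )
        BIG = 1e6
        C = np.where(D <= 0.5, D, BIG)
        rows, cols = linear_sum_assignment(C)
        optimal = int(np.sum(C[rows, cols] < BIG))
        assert len(got) == optimal


class TestCounting:
    def test_blank_nucleus_counts_zero(self, classifier):
        cfg = syn.ScenarioConfig(baseline_rate=0.0)
        rng = np.random.default_rng(1)
        stack, _ = syn.simulate_stack(0.0, 30.0, 1, cfg, rng=rng)
        lm = fp.segment_nuclei(stack)
        record, _ = fp.count_nucleus(stack, lm, lm.ids[0], classifier)
        assert record["dsb_count"] == 0

    def test_counting_invariant_to_intensity_rescaling(self, classifier, small_stack):
        # power-of-two factor: exact in floating point, so the comparison
        # isolates the algorithmic property from threshold rounding flips
        stack, _ = small_stack
        base = fp.count_stack(stack, classifier)
        scaled = fp.count_stack(stack.rescaled(4.0), classifier)
        assert [r["dsb_count"] for r in base] == [r["dsb_count"] for r in scaled]
        # an arbitrary factor may flip borderline threshold pixels; counts
        # must still agree closely
        odd = fp.count_stack(stack.rescaled(3.7), classifier)
        diffs = [abs(a["dsb_count"] - b["dsb_count"]) for a, b in zip(base, odd)]
        assert max(diffs) <= 1

    def test_counting_is_deterministic(self, classifier, small_stack):
        stack, _ = small_stack
        a = fp.count_stack(stack, classifier)
        b = fp.count_stack(stack, classifier)
        assert a == b

    def test_focus_areas_are_pixel_counts(self, classifier, small_stack, small_label_map):
        stack, _ = small_stack
        record, details = fp.count_nucleus(
            stack, small_label_map, small_label_map.ids[0], classifier
        )
        assert len(record["focus_areas_px"]) == record["dsb_count"]
        assert all(isinstance(a, (int, np.integer)) and a >= 1
                   for a in record["focus_areas_px"])
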