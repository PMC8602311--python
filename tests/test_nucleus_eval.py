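"""Segmentation, matching and morphometry against brute-force oracles and
planted ground truth."""

import numpy as np
import pytest
from skimage import measure, segmentation as sks

from rcmstain.nucleus_eval import (SegmentationParams, MatchCounts,
                                   segment_nuclei, expand_objects,
                                   match_objects, sensitivity, precision,
                                   morphology, compactness_of, pcc, ssim,
                                   texture_contrast, evaluate_testset)


class TestSegmentation:
    def test_blank_image_yields_no_objects(self):
        labels, table = segment_nuclei(np.zeros((64, 64)))
        assert labels.max() == 0
        assert len(table) == 0

    def test_planted_nuclei_recovered_with_accurate_centroids(self,
                                                              seg_phantom):
        img = seg_phantom.stained.voxels[1]
        labels, table = segment_nuclei(img)
        gt = sks.clear_border(seg_phantom.nucleus_labels[1])
        n_gt = len(np.unique(gt)) - 1
        counts = match_objects(expand_objects(labels, 4), gt)
        assert counts.n_tp >= 0.9 * n_gt
        gt_centroids = [r.centroid for r in measure.regionprops(gt)]
        errors = []
        for _, row in table.iterrows():
            errors.append(min(np.hypot(row.centroid_y - cy,
                                       row.centroid_x - cx)
                              for cy, cx in gt_centroids))
        assert np.median(errors) < 2.0

    def test_touching_nuclei_are_declumped(self):
        # two overlapping bright disks on a dark background
        img = np.full((96, 96), 0.1)
        yy, xx = np.mgrid[0:96, 0:96]
        for cy, cx in ((48, 38), (48, 52)):
            img[np.hypot(yy - cy, xx - cx) <= 8] = 0.9
        labels, table = segment_nuclei(img, SegmentationParams())
        assert len(table) == 2

    def test_border_objects_discarded(self):
        img = np.full((96, 96), 0.1)
        yy, xx = np.mgrid[0:96, 0:96]
        img[np.hypot(yy - 2, xx - 48) <= 8] = 0.9      # touches top border
        img[np.hypot(yy - 48, xx - 48) <= 8] = 0.9     # interior
        labels, table = segment_nuclei(img)
        assert len(table) == 1
        assert abs(table.iloc[0].centroid_y - 48) < 2

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(diameter_range=(25.0, 10.0)).validate()


class TestExpandObjects:
    def test_zero_radius_is_identity(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[8, 8] = 1
        assert np.array_equal(expand_objects(labels, 0), labels)

    def test_single_pixel_grows_to_discrete_disk(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[16, 16] = 1
        out = expand_objects(labels, 4)
        # brute-force distance scan
        yy, xx = np.mgrid[0:32, 0:32]
        disk = np.hypot(yy - 16, xx - 16) <= 4
        assert np.array_equal(out > 0, disk)
        assert (out > 0).sum() == 49

    def test_nearby_objects_keep_distinct_labels(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[10, 10] = 1
        labels[10, 13] = 2       # 3 px apart
        out = expand_objects(labels, 4)
        assert set(np.unique(out)) == {0, 1, 2}


class TestMatching:
    def test_identical_label_maps_all_true_positive(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[2:6, 2:6] = 1
        labels[20:25, 20:25] = 2
        counts = match_objects(labels, labels)
        assert (counts.n_tp, counts.n_fp, counts.n_fn) == (2, 0, 0)

    def test_disjoint_maps_count_all_errors(self):
        a = np.zeros((32, 32), dtype=int)
        b = np.zeros((32, 32), dtype=int)
        a[2:6, 2:6] = 1
        a[10:14, 10:14] = 2
        b[20:25, 20:25] = 1
        counts = match_objects(a, b)
        assert (counts.n_tp, counts.n_fp, counts.n_fn) == (0, 2, 1)

    def test_hand_checked_five_vs_four_fixture(self):
        pred = np.zeros((40, 40), dtype=int)
        gt = np.zeros((40, 40), dtype=int)
        # three overlapping pairs
        for k, (py, gy) in enumerate(((2, 3), (10, 11), (18, 19)), start=1):
            pred[py:py + 4, 2:6] = k
            gt[gy:gy + 4, 2:6] = k
        pred[30:34, 2:6] = 4        # two predictions with no gt
        pred[30:34, 12:16] = 5
        gt[30:34, 30:34] = 4        # one gt with no prediction
        counts = match_objects(pred, gt)
        assert (counts.n_tp, counts.n_fp, counts.n_fn) == (3, 2, 1)

    def test_matching_conserves_object_counts(self, seg_phantom):
        img = seg_phantom.stained.voxels[1]
        labels, _ = segment_nuclei(img)
        expanded = expand_objects(labels, 4)
        gt = seg_phantom.nucleus_labels[1]
        counts = match_objects(expanded, gt)
        n_pred = len(np.unique(expanded)) - 1
        n_gt = len(np.unique(gt)) - 1
        assert counts.n_tp + counts.n_fp == n_pred
        both = (expanded > 0) & (gt > 0)
        n_matched_gt = len(np.unique(gt[both]))
        assert n_matched_gt + counts.n_fn == n_gt

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_objects(np.zeros((4, 4), int), np.zeros((5, 5), int))


class TestRates:
    def test_sensitivity_and_precision_arithmetic(self):
        assert sensitivity(MatchCounts(8, 0, 2)) == pytest.approx(0.8)
        assert precision(MatchCounts(8, 2, 0)) == pytest.approx(0.8)

    def test_zero_denominators_signal_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            sensitivity(MatchCounts(0, 5, 0))
        with pytest.raises(ValueError, match="undefined"):
            precision(MatchCounts(0, 0, 5))


class TestMorphology:
    def test_single_pixel_object(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[3, 3] = 1
        table = morphology(labels, np.full((8, 8), 0.5))
        row = table.iloc[0]
        assert row.area == 1
        assert row.eccentricity == 0.0
        assert row.integrated_intensity == pytest.approx(0.5)

    def test_disk_has_low_eccentricity(self):
        yy, xx = np.mgrid[0:32, 0:32]
        labels = (np.hypot(yy - 16, xx - 16) <= 6).astype(int)
        table = morphology(labels)
        assert table.iloc[0].eccentricity < 0.2

    def test_bar_eccentric_and_compactness_matches_bruteforce(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[8:11, 4:15] = 1      # 3 x 11 bar
        table = morphology(labels)
        row = table.iloc[0]
        assert row.eccentricity > 0.9
        coords = np.argwhere(labels == 1).astype(float)
        cy, cx = coords.mean(axis=0)
        msd = np.mean([(y - cy) ** 2 + (x - cx) ** 2 for y, x in coords])
        assert row.compactness == pytest.approx(msd / len(coords), rel=1e-9)

    def test_compactness_helper_equals_definition(self, rng):
        coords = rng.integers(0, 16, size=(25, 2)).astype(float)
        c = coords.mean(axis=0)
        expected = np.mean(((coords - c) ** 2).sum(axis=1)) / len(coords)
        assert compactness_of(coords) == pytest.approx(expected, rel=1e-12)


class TestImageSimilarity:
    def test_pcc_identical_images_is_one(self, rng):
        img = rng.random((16, 16))
        assert pcc(img, img) == pytest.approx(1.0)

    def test_pcc_anticorrelated_is_minus_one(self, rng):
        img = rng.random((16, 16))
        assert pcc(img, -img + 0.7) == pytest.approx(-1.0)

    def test_pcc_matches_bruteforce_double_loop(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        ma, mb = a.mean(), b.mean()
        num = sum((a[i, j] - ma) * (b[i, j] - mb)
                  for i in range(16) for j in range(16))
        da = np.sqrt(sum((a[i, j] - ma) ** 2
                         for i in range(16) for j in range(16)))
        db = np.sqrt(sum((b[i, j] - mb) ** 2
                         for i in range(16) for j in range(16)))
        assert pcc(a, b) == pytest.approx(num / (da * db), rel=1e-12)

    def test_pcc_constant_image_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            pcc(np.full((8, 8), 0.5), np.zeros((8, 8)))

    def test_ssim_identical_is_one_and_symmetric(self, seg_phantom, rng):
        img = seg_phantom.stained.voxels[0]
        assert ssim(img, img) == pytest.approx(1.0)
        other = rng.random(img.shape)
        assert ssim(img, other) == pytest.approx(ssim(other, img))

    def test_ssim_inverted_textured_image_is_low(self, seg_phantom):
        img = seg_phantom.stained.voxels[0]
        assert ssim(img, 1.0 - img) < 0.5

    def test_texture_contrast_zero_for_flat_image(self):
        assert texture_contrast(np.full((16, 16), 0.3)) == 0.0


class TestEvaluateTestset:
    def test_perfect_prediction_scores_perfectly(self, seg_phantom):
        imgs = list(seg_phantom.stained.voxels[:2])
        report = evaluate_testset(imgs, imgs)
        assert report["sensitivity"] == 1.0
        assert report["precision"] == 1.0
        assert report["pcc_quartiles"]["median"] == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate_testset([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_testset([np.zeros((8, 8))], [])
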