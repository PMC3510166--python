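"""Pixel features, classifier contract, cleanup and length metric."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import draw as skdraw

import neuritequant as nq
from neuritequant.evaluate import mask_iou
from neuritequant.segmentation import (
    FEATURE_NAMES,
    LABEL_BACKGROUND,
    LABEL_NEURITE,
    MissingDenominatorError,
    SegmentationMap,
    compute_pixel_features,
    skeleton_length,
    train_pixel_classifier,
)
from conftest import ground_truth_label_map


class TestFeatures:
    def test_constant_image_zero_derivative_features(self):
        stack = compute_pixel_features(np.full((64, 64), 11.0))
        assert stack.data.shape == (64, 64, len(FEATURE_NAMES))
        for i, name in enumerate(FEATURE_NAMES):
            if name == "intensity" or name.startswith("gauss"):
                assert np.allclose(stack.data[..., i], 11.0)
            else:
                # zero up to kernel-truncation roundoff
                assert np.allclose(stack.data[..., i], 0.0, atol=0.01)

    def test_ridge_hessian_eigenvalue_peaks_on_centerline(self):
        """|smallest Hessian eigenvalue| of a bright ridge is maximal on
        the centreline; cross-checked with direct finite differences."""
        img = np.zeros((64, 64))
        img[32, :] = 100.0
        img = ndi.gaussian_filter(img, 1.5)
        stack = compute_pixel_features(img)
        idx = FEATURE_NAMES.index("hess_min_s1")
        col = stack.data[10:-10, 32, idx]
        assert np.argmin(col) == 22  # row 32 within the slice
        # finite-difference oracle on the σ=1-smoothed image; the
        # gradient-of-gradient stencil spans ±2 px
        sm = ndi.gaussian_filter(img, 1.0)
        d2 = (sm[30, 32] - 2 * sm[32, 32] + sm[34, 32]) / 4.0
        assert stack.data[32, 32, idx] == pytest.approx(d2, rel=0.05)

    def test_translation_equivariance_interior(self):
        # interior margins exceed the 4σ support of the largest filter
        rng = np.random.default_rng(0)
        img = ndi.gaussian_filter(rng.normal(0, 1, (192, 192)), 2)
        a = compute_pixel_features(img).data
        b = compute_pixel_features(np.roll(img, (5, 3), axis=(0, 1))).data
        assert np.allclose(a[60:120, 60:120], b[65:125, 63:123], atol=1e-4)

    def test_nonfinite_input_rejected(self):
        img = np.zeros((32, 32))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            compute_pixel_features(img)


class TestClassifier:
    def test_single_class_training_rejected(self):
        stack = compute_pixel_features(np.random.default_rng(0)
                                       .normal(size=(32, 32)))
        labels = np.zeros((32, 32), dtype=np.uint8)
        with pytest.raises(ValueError):
            train_pixel_classifier([stack], [labels])

    def test_memorisation_sanity(self):
        """Training and evaluating on the same noiseless scene must be
        nearly perfect per pixel."""
        cfg = nq.SceneConfig(width=128, height=128, n_cells=3, seed=21,
                             poisson_scale=None, gaussian_sd=0.0)
        scene, gt = nq.generate_scene(cfg, nq.PAPER_EFFECTS["Q"],
                                      "neurofilament")
        stack = compute_pixel_features(scene.green)
        labels = ground_truth_label_map(gt)
        clf = train_pixel_classifier([stack], [labels], seed=0,
                                     max_pixels=60_000)
        proba = clf.predict_proba_image(stack)
        pred = clf.model.classes_[np.argmax(proba, axis=-1)]
        assert np.mean(pred == labels) >= 0.99

    def test_heldout_neurite_iou(self, pixel_classifier, small_config):
        """Held-out scenes at default noise: neurite-class IoU vs the
        ground truth must reach 0.7."""
        ious = []
        for seed in range(3):
            scene, gt = nq.generate_scene(
                small_config.replace(seed=700 + seed),
                nq.PAPER_EFFECTS["Q"], "neurofilament")
            segmap = nq.segment(scene.green, pixel_classifier,
                                dapi=scene.dapi,
                                pixel_size=small_config.pixel_size)
            ious.append(mask_iou(segmap.neurite_mask, gt.neurite_mask))
        assert np.mean(ious) >= 0.7

    def test_determinism(self, pixel_classifier, small_config):
        scene, _ = nq.generate_scene(small_config.replace(seed=31),
                                     nq.PAPER_EFFECTS["control"],
                                     "neurofilament")
        a = nq.segment(scene.green, pixel_classifier, dapi=scene.dapi)
        b = nq.segment(scene.green, pixel_classifier, dapi=scene.dapi)
        assert np.array_equal(a.labels, b.labels)
        assert a.nucleus_count == b.nucleus_count

    def test_blank_scene_all_background(self, pixel_classifier):
        rng = np.random.default_rng(1)
        blank = 200.0 + rng.normal(0, 15, (128, 128)) \
            + rng.poisson(50, (128, 128)) / 0.25 - 200.0
        segmap = nq.segment(blank, pixel_classifier)
        assert np.mean(segmap.labels == LABEL_BACKGROUND) > 0.99

    def test_missing_dapi_marks_count_unavailable(self, pixel_classifier,
                                                  small_config):
        scene, _ = nq.generate_scene(small_config.replace(seed=32),
                                     nq.PAPER_EFFECTS["control"],
                                     "neurofilament")
        segmap = nq.segment(scene.green, pixel_classifier, dapi=None)
        assert segmap.nucleus_count is None
        with pytest.raises(MissingDenominatorError):
            nq.neurite_length_per_cell(segmap)


def _segmap_from_mask(mask, nuclei, pixel_size=0.65):
    from skimage.morphology import skeletonize

    labels = np.where(mask, LABEL_NEURITE, LABEL_BACKGROUND).astype(np.uint8)
    return SegmentationMap(labels=labels, nucleus_count=nuclei,
                           skeleton=skeletonize(mask),
                           pixel_size=pixel_size)


class TestLengthMetric:
    def test_empty_mask_zero_length(self):
        segmap = _segmap_from_mask(np.zeros((64, 64), bool), nuclei=3)
        assert nq.neurite_length_per_cell(segmap) == 0.0

    def test_zero_nuclei_raises(self):
        segmap = _segmap_from_mask(np.zeros((64, 64), bool), nuclei=0)
        with pytest.raises(MissingDenominatorError):
            nq.neurite_length_per_cell(segmap)

    def test_horizontal_bar_length(self):
        mask = np.zeros((64, 128), bool)
        mask[30:33, 10:111] = True  # 101 px long, 3 px wide
        segmap = _segmap_from_mask(mask, nuclei=1)
        assert nq.neurite_length_per_cell(segmap) == pytest.approx(
            65.0, abs=2 * 0.65)

    def test_diagonal_bar_length(self):
        mask = np.zeros((128, 128), bool)
        for i in range(101):  # 100 diagonal steps
            rr, cc = skdraw.disk((10 + i, 10 + i), 1.6, shape=mask.shape)
            mask[rr, cc] = True
        segmap = _segmap_from_mask(mask, nuclei=1)
        assert nq.neurite_length_per_cell(segmap) == pytest.approx(
            100 * np.sqrt(2) * 0.65, abs=3 * 0.65)

    def test_rotation_robustness(self):
        """A 100 px bar measured at 0°, 45° and 30°.  The 1/√2 step
        metric is exact for axis-aligned and diagonal lines; at 30° it
        carries the known staircase overestimate of up to ~8%."""
        import math

        lengths = {}
        for ang in (0.0, 45.0, 30.0):
            mask = np.zeros((160, 160), bool)
            for t in np.linspace(0, 100, 401):
                r = 30 + t * math.sin(math.radians(ang))
                c = 20 + t * math.cos(math.radians(ang))
                rr, cc = skdraw.disk((r, c), 1.6, shape=mask.shape)
                mask[rr, cc] = True
            segmap = _segmap_from_mask(mask, nuclei=1, pixel_size=1.0)
            lengths[ang] = nq.neurite_length_per_cell(segmap)
        assert lengths[45.0] == pytest.approx(lengths[0.0], rel=0.05)
        assert lengths[30.0] == pytest.approx(lengths[0.0], rel=0.08)

    def test_skeleton_length_straight_segment_steps(self):
        sk = np.zeros((16, 16), bool)
        sk[4, 2:12] = True  # 10 px -> 9 steps
        assert skeleton_length(sk, 1.0) == pytest.approx(9.0)


class TestFoldRecovery:
    def test_monotone_in_length_multiplier(self, pixel_classifier,
                                           small_config):
        """Measured neurite length/cell must increase strictly with the
        configured multiplier (1 vs 1.5 vs 3, averaged over scenes)."""
        means = []
        for mult_cond in ("control", "Q", "Q+Y27632"):
            vals = []
            for seed in range(4):
                scene, _ = nq.generate_scene(
                    small_config.replace(seed=800 + seed),
                    nq.PAPER_EFFECTS[mult_cond], "neurofilament")
                segmap = nq.segment(scene.green, pixel_classifier,
                                    dapi=scene.dapi,
                                    pixel_size=small_config.pixel_size)
                vals.append(nq.neurite_length_per_cell(segmap))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_fold_change_recovery_within_15_percent(self, pixel_classifier,
                                                    small_config):
        folds = {}
        for cond in ("control", "Q"):
            vals = []
            for seed in range(6):
                scene, _ = nq.generate_scene(
                    small_config.replace(seed=850 + seed),
                    nq.PAPER_EFFECTS[cond], "neurofilament")
                segmap = nq.segment(scene.green, pixel_classifier,
                                    dapi=scene.dapi,
                                    pixel_size=small_config.pixel_size)
                vals.append(nq.neurite_length_per_cell(segmap))
            folds[cond] = np.mean(vals)
        measured = folds["Q"] / folds["control"]
        assert measured == pytest.approx(1.5, rel=0.15)
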