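"""Segmentation primitives: classifier, rolling ball, erosion, labeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmequant.segmorph import (
    erode_mask,
    label_and_filter,
    predict_mask,
    rolling_ball_subtract,
    train_pixel_classifier,
)


def _two_intensity_image(rng, fg=1000.0, bg=100.0, sd=10.0, shape=(64, 64)):
    truth = np.zeros(shape, dtype=bool)
    truth[16:48, 20:52] = True
    img = np.where(truth, fg, bg) + rng.normal(0, sd, shape)
    return np.clip(img, 0, None), truth


def _sparse_annotations(truth, rng, n_per_class=200):
    labels = np.zeros(truth.shape, dtype=np.int8)
    fg_idx = np.flatnonzero(truth.ravel())
    bg_idx = np.flatnonzero(~truth.ravel())
    labels.ravel()[rng.choice(fg_idx, n_per_class, replace=False)] = 2
    labels.ravel()[rng.choice(bg_idx, n_per_class, replace=False)] = 1
    return labels


class TestPixelClassifier:
    def test_two_intensity_benchmark_iou(self, rng):
        img, truth = _two_intensity_image(rng)
        clf = train_pixel_classifier([img], [_sparse_annotations(truth, rng)], seed=0)
        pred = predict_mask(clf, img, target_class=2)
        iou = (pred & truth).sum() / (pred | truth).sum()
        assert iou >= 0.95

    def test_same_seed_identical_predictions(self, rng):
        img, truth = _two_intensity_image(rng)
        ann = _sparse_annotations(truth, rng)
        a = train_pixel_classifier([img], [ann], seed=3).predict(img)
        b = train_pixel_classifier([img], [ann], seed=3).predict(img)
        np.testing.assert_array_equal(a, b)

    def test_single_class_annotations_rejected(self, rng):
        img, truth = _two_intensity_image(rng)
        ann = np.zeros_like(img, dtype=np.int8)
        ann[truth] = 1
        with pytest.raises(ValueError, match="2 annotated classes"):
            train_pixel_classifier([img], [ann])

    def test_probabilities_sum_to_one(self, rng):
        img, truth = _two_intensity_image(rng, shape=(32, 32))
        clf = train_pixel_classifier([img], [_sparse_annotations(truth, rng, 50)])
        proba = clf.predict_proba(img)
        assert proba.shape == img.shape + (2,)
        np.testing.assert_allclose(proba.sum(axis=-1), 1.0, atol=1e-12)

    def test_serialization_roundtrip(self, rng, tmp_path):
        from pmequant.segmorph import PixelClassifier

        img, truth = _two_intensity_image(rng, shape=(32, 32))
        clf = train_pixel_classifier([img], [_sparse_annotations(truth, rng, 50)])
        clf.save(tmp_path / "clf.joblib")
        back = PixelClassifier.load(tmp_path / "clf.joblib")
        np.testing.assert_array_equal(back.predict(img), clf.predict(img))

    def test_constant_image_matching_exemplar_is_uniform(self, rng):
        img = np.concatenate(
            [np.full((16, 32), 100.0), np.full((16, 32), 1000.0)], axis=0
        )
        ann = np.zeros_like(img, dtype=np.int8)
        ann[2:6, 2:6] = 1  # background exemplar
        ann[20:24, 2:6] = 2  # foreground exemplar
        clf = train_pixel_classifier([img], [ann], seed=0)
        pred = clf.predict(np.full((10, 10), 1000.0))
        assert np.all(pred == 2)
        assert not predict_mask(clf, np.full((10, 10), 100.0), 2).any()

    def test_3d_axoneme_tube_dice(self):
        """Classifier segments the synthetic axoneme tube at Dice >= 0.9."""
        from pmequant import synthgen as sg

        params = sg.Scene3DParams(shape=(16, 48, 48), n_puncta=0, seed=13)
        stack, _ = sg.make_axoneme_volume_3d(params)
        channel = stack.channel("axoneme")
        truth = channel > params.background + 10 * params.noise_sd
        rng = np.random.default_rng(5)
        ann = np.zeros(channel.shape, dtype=np.int8)
        fg = np.flatnonzero(truth.ravel())
        bg = np.flatnonzero(~truth.ravel())
        ann.ravel()[rng.choice(fg, 100, replace=False)] = 2
        ann.ravel()[rng.choice(bg, 300, replace=False)] = 1
        clf = train_pixel_classifier([channel], [ann], seed=0)
        pred = predict_mask(clf, channel, 2)
        dice = 2 * (pred & truth).sum() / (pred.sum() + truth.sum())
        assert dice >= 0.9

    @pytest.mark.parametrize("separation_sd", [5.0, 8.0])
    def test_accuracy_beats_bayes_floor(self, rng, separation_sd):
        """Two-Gaussian benchmark: accuracy within 5 points of the Bayes rate."""
        from scipy.stats import norm

        sd = 20.0
        img, truth = _two_intensity_image(rng, fg=500 + separation_sd * sd, bg=500, sd=sd)
        clf = train_pixel_classifier([img], [_sparse_annotations(truth, rng)], seed=1)
        pred = predict_mask(clf, img, target_class=2)
        accuracy = (pred == truth).mean()
        bayes = norm.cdf(separation_sd / 2)
        assert accuracy >= bayes - 0.05


def _opening_oracle(image: np.ndarray, radius: int) -> np.ndarray:
    """Brute-force grayscale opening with a disk: reflect-padded min then max."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = (yy * yy + xx * xx) <= radius * radius
    offs = np.argwhere(disk) - radius

    def _apply(img, reducer):
        pad = np.pad(img, radius, mode="reflect")
        stacks = np.stack(
            [
                pad[radius + dy : radius + dy + img.shape[0],
                    radius + dx : radius + dx + img.shape[1]]
                for dy, dx in offs
            ]
        )
        return reducer(stacks, axis=0)

    return _apply(_apply(image, np.min), np.max)


class TestRollingBall:
    def test_constant_image_maps_to_zero(self):
        out = rolling_ball_subtract(np.full((40, 40), 123.0), 35)
        np.testing.assert_array_equal(out, 0.0)

    def test_narrow_peak_preserved(self):
        img = np.full((80, 80), 100.0)
        img[40, 40] += 500.0
        out = rolling_ball_subtract(img, 35)
        assert out[40, 40] == pytest.approx(500.0, rel=0.01)

    def test_broad_plateau_removed(self):
        img = np.zeros((200, 200))
        img[20:180, 20:180] = 300.0  # plateau much wider than 2×radius
        out = rolling_ball_subtract(img, 35)
        assert out[100, 100] <= 3.0  # ≤1% residual at center

    @pytest.mark.parametrize("radius", [3, 10, 35])
    def test_matches_opening_oracle(self, rng, radius):
        img = rng.uniform(0, 1000, (64, 64))
        out = rolling_ball_subtract(img, radius)
        expected = np.clip(img - _opening_oracle(img, radius), 0, None)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_translation_equivariance(self, rng):
        img = rng.uniform(0, 500, (48, 48))
        shifted = np.roll(img, (5, 7), axis=(0, 1))
        # compare well away from wrap-around and reflect-boundary bands
        # (both extend 2×radius = 8 px, plus the 5/7 px roll)
        a = np.roll(rolling_ball_subtract(img, 4), (5, 7), axis=(0, 1))
        b = rolling_ball_subtract(shifted, 4)
        np.testing.assert_allclose(a[16:36, 16:36], b[16:36, 16:36], atol=1e-9)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            rolling_ball_subtract(np.zeros((8, 8)), 0)


class TestErodeMask:
    def test_40_square_eroded_15_leaves_10_square(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 10:50] = True
        out = erode_mask(mask, 15)
        expected = np.zeros_like(mask)
        expected[25:35, 25:35] = True
        np.testing.assert_array_equal(out, expected)

    def test_erosion_by_zero_is_identity(self, rng):
        mask = rng.random((30, 30)) > 0.5
        np.testing.assert_array_equal(erode_mask(mask, 0), mask)

    def test_20_square_eroded_15_is_empty(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        assert not erode_mask(mask, 15).any()

    def test_retained_pixels_far_from_boundary(self, rng):
        """Brute-force check: retained ⇔ Euclidean distance to every
        background pixel exceeds the radius."""
        mask = np.zeros((24, 24), dtype=bool)
        mask[4:20, 6:22] = True
        mask[10, 10] = False  # a hole
        radius = 3
        out = erode_mask(mask, radius)
        bg = np.argwhere(~mask)
        for y, x in np.argwhere(mask):
            d = np.sqrt(((bg - (y, x)) ** 2).sum(axis=1)).min()
            assert out[y, x] == (d > radius)

    @given(radius=st.integers(0, 6), bigger=st.integers(1, 4))
    @settings(max_examples=20, deadline=None)
    def test_anti_extensive_and_monotone(self, radius, bigger):
        rng = np.random.default_rng(99)
        mask = rng.random((20, 20)) > 0.3
        small = erode_mask(mask, radius)
        large = erode_mask(mask, radius + bigger)
        assert np.all(small <= mask)
        assert np.all(large <= small)


class TestLabelAndFilter:
    def test_small_component_filtered(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:12, 2:12] = True  # 100 px
        mask[20:25, 20] = True  # 5 px
        objs = label_and_filter(mask, min_size_px=10)
        assert objs.n_objects == 1
        assert objs.table["voxel_count"].iloc[0] == 100

    def test_empty_mask_zero_objects(self):
        objs = label_and_filter(np.zeros((10, 10), dtype=bool))
        assert objs.n_objects == 0

    def test_sphere_just_under_15um3_filtered(self):
        """r=1.5 µm sphere in 0.25 µm voxels has true volume ≈14.1 µm³ < 15."""
        spacing = (0.25, 0.25, 0.25)
        zz, yy, xx = np.mgrid[0:24, 0:24, 0:24].astype(float) * 0.25
        mask = (zz - 3) ** 2 + (yy - 3) ** 2 + (xx - 3) ** 2 <= 1.5**2
        # voxel-count oracle: the discrete volume must itself be < 15 µm³
        assert mask.sum() * 0.25**3 < 15.0
        objs = label_and_filter(mask, spacing=spacing, min_volume_um3=15.0)
        assert objs.n_objects == 0

    def test_diagonal_connectivity_2d_is_8(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert label_and_filter(mask).n_objects == 1

    def test_volume_equals_count_times_voxel_volume(self, rng):
        mask = rng.random((12, 14, 16)) > 0.7
        spacing = (0.5, 0.25, 0.25)
        objs = label_and_filter(mask, spacing=spacing)
        vv = 0.5 * 0.25 * 0.25
        total = objs.table["volume_um3"].sum()
        assert total == pytest.approx(mask.sum() * vv)
        np.testing.assert_allclose(
            objs.table["volume_um3"], objs.table["voxel_count"] * vv
        )

    def test_labels_dense_and_raster_ordered(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[8, 8] = True
        mask[1, 1] = True
        mask[4:6, 3:5] = True
        objs = label_and_filter(mask)
        assert list(objs.table["label"]) == [1, 2, 3]
        # first object in raster order is the (1,1) pixel
        assert objs.labels[1, 1] == 1
        assert objs.labels[8, 8] == 3

    def test_intensity_summaries(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[0:2, 0:2] = True
        signal = np.arange(36, dtype=float).reshape(6, 6)
        objs = label_and_filter(mask, intensity_channels={"md": signal})
        assert objs.table["mean_md"].iloc[0] == pytest.approx((0 + 1 + 6 + 7) / 4)
        assert objs.table["total_md"].iloc[0] == pytest.approx(14.0)
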