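"""Distance shells, object filtering, membrane ratio, envelope background."""

import numpy as np
import pytest

from pmequant.segmorph import label_and_filter
from pmequant.shell3d import (
    compute_shells,
    filter_smallest_objects,
    guarded_background_mean,
    membrane_axoneme_ratio,
    shell_volume_profile,
)


def brute_force_shells(ref: np.ndarray, spacing, K: int, w: float) -> np.ndarray:
    """All-pairs voxel-center distance oracle for shell labels."""
    ref = np.asarray(ref, dtype=bool)
    sp = np.asarray(spacing)
    ref_coords = np.argwhere(ref) * sp
    shell = np.zeros(ref.shape, dtype=np.int32)
    for idx in np.ndindex(ref.shape):
        if ref[idx]:
            continue
        d = np.sqrt(((ref_coords - np.asarray(idx) * sp) ** 2).sum(axis=1)).min()
        k = int(np.ceil(np.round(d / w, 9)))
        shell[idx] = k if k <= K else -1
    return shell


class TestComputeShells:
    def test_single_voxel_shell1_is_face_neighbors(self):
        ref = np.zeros((5, 5, 5), dtype=bool)
        ref[2, 2, 2] = True
        part = compute_shells(ref, (1.0, 1.0, 1.0), shell_count=1, shell_width_um=1.0)
        shell1 = part.shell_map == 1
        assert shell1.sum() == 6
        assert shell1[1, 2, 2] and shell1[3, 2, 2] and shell1[2, 1, 2]
        assert not shell1[1, 1, 2]  # diagonal at sqrt(2) is beyond shell 1

    @pytest.mark.parametrize(
        "shape,spacing",
        [((15, 15, 15), (1.0, 1.0, 1.0)), ((12, 16, 20), (0.5, 0.25, 0.25))],
    )
    def test_matches_brute_force_oracle(self, rng, shape, spacing):
        ref = np.zeros(shape, dtype=bool)
        ref[tuple(rng.integers(0, s, 5) for s in shape)] = True
        part = compute_shells(ref, spacing, shell_count=4, shell_width_um=1.0)
        expected = brute_force_shells(ref, spacing, 4, 1.0)
        np.testing.assert_array_equal(part.shell_map, expected)

    def test_straight_axoneme_oracle_equality(self):
        ref = np.zeros((9, 21, 21), dtype=bool)
        ref[4, 10, 3:18] = True
        part = compute_shells(ref, (0.5, 0.5, 0.5), shell_count=3, shell_width_um=1.0)
        expected = brute_force_shells(ref, (0.5, 0.5, 0.5), 3, 1.0)
        np.testing.assert_array_equal(part.shell_map, expected)

    def test_one_huge_shell_covers_everything(self):
        ref = np.zeros((8, 8, 8), dtype=bool)
        ref[4, 4, 4] = True
        part = compute_shells(ref, (1, 1, 1), shell_count=1, shell_width_um=100.0)
        assert (part.shell_map == 1).sum() == 8**3 - 1

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_shells(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1))

    def test_cylinder_shell_volumes_converge(self):
        """Shell volumes around a straight cylinder approach the analytic
        annulus volume as voxel spacing halves (error shrinks ~2×)."""
        r, w, length = 0.5, 1.0, 8.0

        def measured_error(h):
            n = int(round(length / h))
            half = int(round(6.0 / h))
            ref = np.zeros((2 * half + 1, 2 * half + 1, n), dtype=bool)
            zz, yy = np.mgrid[-half : half + 1, -half : half + 1].astype(float) * h
            disk = zz**2 + yy**2 <= r**2
            ref[disk] = True
            part = compute_shells(ref, (h, h, h), shell_count=1, shell_width_um=w)
            measured = part.shell_volumes_um3[0] / length
            analytic = np.pi * ((r + w) ** 2 - r**2)
            return abs(measured - analytic) / analytic

        e_coarse, e_fine = measured_error(0.25), measured_error(0.125)
        assert e_fine < 0.6 * e_coarse


class TestFilterSmallestObjects:
    @staticmethod
    def _objects_with_volumes(volumes):
        """One-voxel-per-row objects with prescribed µm³ volumes via spacing=1
        and repeated voxels along x."""
        n = len(volumes)
        width = max(volumes)
        mask = np.zeros((n * 2, width + 2), dtype=bool)
        for i, v in enumerate(volumes):
            mask[i * 2, 1 : 1 + v] = True
        return label_and_filter(mask, spacing=(1.0, 1.0))

    def test_volumes_1_to_10_fraction_04(self):
        objs = self._objects_with_volumes(list(range(1, 11)))
        kept, retained = filter_smallest_objects(objs, 0.40)
        assert kept.n_objects == 6
        assert set(kept.table["volume_um3"]) == {5, 6, 7, 8, 9, 10}
        # arithmetic oracle: removed volume 1+2+3+4 = 10 of 55
        assert retained == pytest.approx(45 / 55)

    def test_single_object_untouched(self):
        objs = self._objects_with_volumes([4])
        kept, retained = filter_smallest_objects(objs, 0.40)
        assert kept.n_objects == 1 and retained == 1.0

    def test_equal_volumes_tie_broken_by_label(self):
        objs = self._objects_with_volumes([3] * 10)
        kept, retained = filter_smallest_objects(objs, 0.40)
        assert kept.n_objects == 6
        assert retained == pytest.approx(0.6)
        # labels 1..4 (raster-first) removed
        assert kept.labels[0, 1] == 0 and kept.labels[2, 1] == 0


class TestShellVolumeProfile:
    def test_constructed_object_in_shell_3(self):
        ref = np.zeros((20, 30, 30), dtype=bool)
        ref[10, 15, 15] = True
        part = compute_shells(ref, (1, 1, 1), shell_count=5, shell_width_um=1.0)
        mask = np.zeros_like(ref)
        shell3 = part.shell_map == 3
        coords = np.argwhere(shell3)[:10]
        mask[tuple(coords.T)] = True
        objs = label_and_filter(mask, spacing=(1, 1, 1))
        profile = shell_volume_profile(objs, part)
        expected = np.zeros(5)
        expected[2] = 10 / shell3.sum()
        np.testing.assert_allclose(profile.normalized_volume, expected)

    def test_no_objects_zero_profile(self):
        ref = np.zeros((6, 6, 6), dtype=bool)
        ref[3, 3, 3] = True
        part = compute_shells(ref, (1, 1, 1), shell_count=3, shell_width_um=1.0)
        objs = label_and_filter(np.zeros_like(ref), spacing=(1, 1, 1))
        profile = shell_volume_profile(objs, part)
        np.testing.assert_array_equal(profile.normalized_volume, 0.0)

    def test_volume_conservation_within_range(self, rng):
        ref = np.zeros((12, 12, 12), dtype=bool)
        ref[6, 6, 6] = True
        part = compute_shells(ref, (1, 1, 1), shell_count=20, shell_width_um=1.0)
        mask = rng.random(ref.shape) > 0.6
        mask &= ~ref
        objs = label_and_filter(mask, spacing=(1, 1, 1))
        profile = shell_volume_profile(objs, part)
        assert profile.signal_volume_um3.sum() == pytest.approx(mask.sum())


class TestMembraneAxonemeRatio:
    def _scene(self):
        ax = np.zeros((5, 7, 30), dtype=bool)
        ax[2, 3, 5:25] = True  # 20-voxel axoneme
        return ax

    def test_adjacent_membrane_counts(self):
        ax = self._scene()
        mem = np.zeros_like(ax)
        mem[2, 4, 5:15] = True  # 10 voxels touching
        objs = label_and_filter(mem, spacing=(1, 1, 1))
        assert membrane_axoneme_ratio(objs, ax, (1, 1, 1)) == pytest.approx(0.5)

    def test_distant_membrane_ignored(self):
        ax = self._scene()
        mem = np.zeros_like(ax)
        mem[2, 6, 5:15] = True  # 3 voxels away in y
        objs = label_and_filter(mem, spacing=(1, 1, 1))
        assert membrane_axoneme_ratio(objs, ax, (1, 1, 1)) == 0.0

    def test_mixed_objects_touching_rule(self):
        ax = np.zeros((3, 9, 30), dtype=bool)
        ax[1, 1, 0:20] = True  # 20-voxel axoneme
        mem = np.zeros_like(ax)
        mem[1, 2, 0:10] = True  # touching: 10 voxels (diagonal adjacency in y)
        mem[1, 7, 0:30] = True  # distant: 30 voxels
        objs = label_and_filter(mem, spacing=(1, 1, 1))
        assert membrane_axoneme_ratio(objs, ax, (1, 1, 1)) == pytest.approx(0.5)

    def test_empty_axoneme_rejected(self):
        objs = label_and_filter(np.zeros((3, 3, 3), dtype=bool), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="axoneme"):
            membrane_axoneme_ratio(objs, np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))

    def test_physical_touch_distance(self):
        ax = self._scene()
        mem = np.zeros_like(ax)
        mem[2, 5, 5:15] = True  # 2 voxels away
        objs = label_and_filter(mem, spacing=(1, 1, 1))
        assert membrane_axoneme_ratio(objs, ax, (1, 1, 1)) == 0.0
        assert membrane_axoneme_ratio(objs, ax, (1, 1, 1), touch_distance_um=2.5) == pytest.approx(0.5)


class TestGuardedBackgroundMean:
    def test_plain_difference(self):
        target = np.zeros((9, 9, 9), dtype=bool)
        target[4, 4, 4] = True
        signal = np.full((9, 9, 9), 100.0)
        signal[4, 4, 4] = 500.0
        raw, bg, norm = guarded_background_mean(target, signal, 0.5, 1.0, (1, 1, 1))
        assert (raw, bg, norm) == (500.0, 100.0, 400.0)

    def test_uniform_image_normalizes_to_zero(self):
        target = np.zeros((7, 7, 7), dtype=bool)
        target[3, 3, 3] = True
        _, _, norm = guarded_background_mean(
            target, np.full((7, 7, 7), 42.0), 0.5, 1.0, (1, 1, 1)
        )
        assert norm == 0.0

    def test_guard_shell_excluded_from_background(self):
        target = np.zeros((11, 11, 11), dtype=bool)
        target[5, 5, 5] = True
        signal = np.full((11, 11, 11), 10.0)
        # poison the guard shell (distance <= 1); background must ignore it
        dist_one = np.zeros_like(target)
        dist_one[4:7, 4:7, 4:7] = True
        dist_one[5, 5, 5] = False
        signal[dist_one] = 9000.0
        _, bg, _ = guarded_background_mean(target, signal, 1.8, 1.5, (1, 1, 1))
        assert bg == 10.0

    def test_empty_background_shell_rejected(self):
        target = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError, match="background"):
            guarded_background_mean(target, np.zeros((3, 3, 3)), 0.5, 1.0, (1, 1, 1))
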