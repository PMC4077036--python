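"""Building blocks and the six segmentation methods, validated against
exhaustive oracles and synthetic ground truth."""

import numpy as np
import pytest

from nucseg.dogfilter import DoGSpec, dog_response
from nucseg.imgdata import ImageStack, LabelVolume, VoxelSpacing
from nucseg.segmenters import (
    METHOD_NAMES,
    MethodParams,
    distance_map,
    find_local_maxima,
    local_threshold,
    region_centroids,
    segment,
    segment_dst,
    segment_hyb,
    segment_locreg,
    segment_locwat,
    size_filter,
    watershed_transform,
    _rescale01,
)
from nucseg.synthgen import SynthConfig, render_frame

from oracles import (
    canonical_labels,
    local_maxima_oracle,
    mutual_nn_oracle,
    nearest_background_um,
    priority_flood_oracle,
    windowed_mean,
)

SPACING = VoxelSpacing()


# ---------------------------------------------------------------------------
# local_threshold
# ---------------------------------------------------------------------------

class TestLocalThreshold:
    def test_constant_image_positive_offset_all_background(self):
        stack = ImageStack(np.full((6, 10, 10), 0.4), SPACING)
        assert not local_threshold(stack, win=2.0, offset=0.01).any()

    def test_bright_cube_recovered_with_wide_window(self):
        arr = np.zeros((8, 20, 20))
        arr[3:5, 8:12, 8:12] = 1.0
        stack = ImageStack(arr, SPACING)
        mask = local_threshold(stack, win=3.0, offset=0.0)
        np.testing.assert_array_equal(mask, arr > 0)

    def test_window_covering_volume_equals_global_mean(self, rng):
        arr = rng.random((4, 8, 8))
        stack = ImageStack(arr, SPACING)
        mask = local_threshold(stack, win=100.0, offset=0.05)
        np.testing.assert_array_equal(mask, arr > arr.mean() + 0.05)

    def test_matches_brute_force_windowed_mean(self, rng):
        arr = rng.random((5, 9, 9))
        stack = ImageStack(arr, SPACING)
        win, offset = 1.5, 0.02
        sizes = []
        for d, n in zip(SPACING.zyx, arr.shape):
            hw = max(1, round(win / (2 * d)))
            sizes.append(min(2 * hw + 1, n if n % 2 else n - 1))
        expected = arr > windowed_mean(arr, tuple(sizes)) + offset
        np.testing.assert_array_equal(local_threshold(stack, win, offset), expected)


# ---------------------------------------------------------------------------
# distance_map
# ---------------------------------------------------------------------------

class TestDistanceMap:
    def test_single_voxel_distance_is_xy_step(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        dist = distance_map(mask, SPACING)
        assert dist[2, 2, 2] == pytest.approx(0.25)
        assert dist[~mask].max() == 0.0

    def test_border_counts_as_background(self):
        mask = np.ones((3, 9, 9), bool)
        dist = distance_map(mask, SPACING)
        # center voxel: 5 xy steps (1.25 um) to the side faces beat 2 z steps (2 um)
        assert dist[1, 4, 4] == pytest.approx(1.25)
        assert dist[0, 0, 0] == pytest.approx(0.25)

    def test_anisotropic_spacing_matches_exhaustive_search(self, rng):
        spacing = VoxelSpacing(dx=0.3, dy=0.7, dz=1.9)
        mask = rng.random((5, 5, 5)) > 0.4
        np.testing.assert_allclose(
            distance_map(mask, spacing),
            nearest_background_um(mask, spacing.zyx),
            atol=1e-10,
        )

    def test_distances_scale_with_spacing(self, rng):
        mask = rng.random((4, 6, 6)) > 0.5
        d1 = distance_map(mask, VoxelSpacing(0.25, 0.25, 1.0))
        d2 = distance_map(mask, VoxelSpacing(0.5, 0.5, 2.0))
        np.testing.assert_allclose(d2, 2.0 * d1, atol=1e-10)

    def test_matches_exhaustive_search(self, rng):
        mask = rng.random((4, 6, 6)) > 0.5
        np.testing.assert_allclose(
            distance_map(mask, SPACING),
            nearest_background_um(mask, SPACING.zyx),
            atol=1e-10,
        )


# ---------------------------------------------------------------------------
# find_local_maxima
# ---------------------------------------------------------------------------

class TestLocalMaxima:
    def test_single_blob_yields_peak_voxel(self):
        cfg = SynthConfig(
            shape=(16, 32, 32), schedule=[(0, 1)], diameter_um=4.5,
            noise_sigma=0.0, shot_scale=0.0, seed=0,
        )
        stack, centers = render_frame(np.array([[8.0, 4.0, 4.0]]), cfg, diameter_um=4.5)
        pts = find_local_maxima(stack, radius=2.0, min_intensity=0.2)
        assert len(pts) == 1
        np.testing.assert_array_equal(pts[0], [8, 16, 16])

    def test_flat_plateau_keeps_one_point(self):
        arr = np.zeros((3, 9, 9))
        arr[1, 3:6, 3:6] = 0.8
        pts = find_local_maxima(ImageStack(arr, SPACING), radius=2.0, min_intensity=0.5)
        assert len(pts) == 1
        np.testing.assert_array_equal(pts[0], [1, 3, 3])  # lexicographically smallest

    def test_blob_separation_vs_radius(self):
        arr = np.zeros((5, 40, 40))
        arr[2, 10, 10] = 1.0
        arr[2, 10, 30] = 0.9  # 5 um away in x
        far = find_local_maxima(ImageStack(arr, SPACING), radius=4.0, min_intensity=0.1)
        assert len(far) == 2
        near = find_local_maxima(ImageStack(arr, SPACING), radius=6.0, min_intensity=0.1)
        assert len(near) == 1 and tuple(near[0]) == (2, 10, 10)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            arr = np.round(rng.random((4, 7, 7)), 2)  # rounding forces ties
            pts = find_local_maxima(ImageStack(arr, SPACING), radius=0.6, min_intensity=0.3)
            expected = local_maxima_oracle(arr, SPACING.zyx, 0.6, 0.3)
            assert [tuple(p) for p in pts] == expected


# ---------------------------------------------------------------------------
# watershed_transform
# ---------------------------------------------------------------------------

class TestWatershed:
    def test_two_basins_split_at_ridge(self):
        z = np.zeros((1, 5, 11))
        x = np.arange(11, dtype=float)
        z[0, :, :] = np.minimum((x - 2) ** 2, (x - 8) ** 2)  # ridge at x=5
        vol = watershed_transform(z)
        labels = vol.labels
        assert vol.n_labels == 2
        oracle = priority_flood_oracle(z)
        np.testing.assert_array_equal(canonical_labels(labels), canonical_labels(oracle))
        assert (labels[0, :, :5] == labels[0, 0, 2]).all()
        assert (labels[0, :, 6:] == labels[0, 0, 8]).all()

    def test_uniform_landscape_connected_mask_one_label(self):
        mask = np.zeros((3, 6, 6), bool)
        mask[1, 1:5, 1:5] = True
        vol = watershed_transform(np.zeros((3, 6, 6)), mask=mask)
        assert vol.n_labels == 1
        assert (vol.labels[mask] == 1).all() and (vol.labels[~mask] == 0).all()

    def test_two_seeds_partition_connected_mask(self, rng):
        landscape = rng.random((4, 6, 6))
        mask = np.ones((4, 6, 6), bool)
        seeds = np.zeros((4, 6, 6), np.int32)
        seeds[0, 0, 0] = 1
        seeds[3, 5, 5] = 2
        vol = watershed_transform(landscape, seeds=seeds, mask=mask)
        assert vol.n_labels == 2
        assert vol.labels[0, 0, 0] == 1 and vol.labels[3, 5, 5] == 2
        assert (vol.labels[mask] > 0).all()

    def test_seed_outside_mask_rejected(self):
        seeds = np.zeros((2, 3, 3), np.int32)
        seeds[0, 0, 0] = 1
        mask = np.zeros((2, 3, 3), bool)
        mask[1] = True
        with pytest.raises(ValueError, match="outside mask"):
            watershed_transform(np.zeros((2, 3, 3)), seeds=seeds, mask=mask)

    def test_agrees_with_priority_flood_oracle_random(self, rng):
        """100 random small landscapes, mixed masked/seeded/unseeded."""
        for trial in range(100):
            shape = tuple(rng.integers(2, (4, 6, 6), endpoint=True))
            landscape = np.round(rng.random(shape), 1)  # coarse values force ties
            mask = None
            seeds = None
            if trial % 3 == 1:
                mask = rng.random(shape) > 0.2
            if trial % 3 == 2:
                seeds = np.zeros(shape, np.int32)
                for lab in (1, 2):
                    seeds[tuple(rng.integers(0, shape))] = lab
            got = watershed_transform(landscape, seeds=seeds, mask=mask).labels
            expected = priority_flood_oracle(landscape, seeds=seeds, mask=mask)
            np.testing.assert_array_equal(
                canonical_labels(got), canonical_labels(expected),
                err_msg=f"trial {trial}",
            )

    def test_deterministic_across_runs(self, rng):
        landscape = rng.random((5, 8, 8))
        a = watershed_transform(landscape).labels
        b = watershed_transform(landscape.copy()).labels
        np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# size_filter and centroids
# ---------------------------------------------------------------------------

class TestSizeFilter:
    def _volume_with_region(self, n_voxels):
        labs = np.zeros((3, 10, 10), np.int32)
        labs[1].flat[:n_voxels] = 1
        return LabelVolume(labs)

    def test_region_below_threshold_removed(self):
        assert size_filter(self._volume_with_region(10), 11).n_labels == 0

    def test_region_at_threshold_kept(self):
        """Strictly-below rule: exactly min_voxels voxels survive."""
        assert size_filter(self._volume_with_region(10), 10).n_labels == 1

    def test_raising_threshold_never_adds_regions(self, rng):
        labs = (rng.random((4, 12, 12)) > 0.7).astype(np.int32)
        from scipy import ndimage
        labs, _ = ndimage.label(labs, structure=np.ones((3, 3, 3)))
        vol = LabelVolume(labs.astype(np.int32))
        counts = [size_filter(vol, m).n_labels for m in (0, 2, 4, 8, 16)]
        assert counts == sorted(counts, reverse=True)

    def test_disconnected_label_splits(self):
        labs = np.zeros((1, 1, 7), np.int32)
        labs[0, 0, 0:2] = 1
        labs[0, 0, 5:7] = 1  # same label, not 26-connected
        out = size_filter(LabelVolume(labs), 1)
        assert out.n_labels == 2

    def test_touching_distinct_labels_not_merged(self):
        labs = np.zeros((1, 1, 6), np.int32)
        labs[0, 0, :3] = 1
        labs[0, 0, 3:] = 2
        out = size_filter(LabelVolume(labs), 1)
        assert out.n_labels == 2

    def test_labels_contiguous_after_filtering(self):
        labs = np.zeros((1, 1, 9), np.int32)
        labs[0, 0, 0] = 1          # too small, removed
        labs[0, 0, 2:5] = 2
        labs[0, 0, 6:9] = 3
        out = size_filter(LabelVolume(labs), 2)
        assert sorted(np.unique(out.labels[out.labels > 0])) == [1, 2]


class TestRegionCentroids:
    def test_single_voxel_position(self):
        labs = np.zeros((5, 8, 8), np.int32)
        labs[2, 4, 4] = 1
        (det,) = region_centroids(LabelVolume(labs, SPACING))
        assert det.centroid == (1.0, 1.0, 2.0)  # x, y, z um
        assert det.voxels == 1

    def test_symmetric_cube_centroid_at_center(self):
        labs = np.zeros((7, 9, 9), np.int32)
        labs[2:5, 3:6, 3:6] = 1
        (det,) = region_centroids(LabelVolume(labs, SPACING))
        assert det.centroid == (4 * 0.25, 4 * 0.25, 3.0)

    def test_random_region_matches_direct_average(self, rng):
        labs = np.zeros((6, 10, 10), np.int32)
        idx = rng.random((6, 10, 10)) > 0.8
        labs[idx] = 1
        (det,) = region_centroids(LabelVolume(labs, SPACING))
        coords = np.argwhere(idx) * np.asarray(SPACING.zyx)
        np.testing.assert_allclose(
            det.centroid, coords.mean(axis=0)[::-1], atol=1e-12
        )
        assert det.voxels == idx.sum()


# ---------------------------------------------------------------------------
# the six methods: shared battery on synthetic nuclei
# ---------------------------------------------------------------------------

def _render_nuclei(centers_um, shape=(30, 96, 96), diameter=4.5, seed=3):
    cfg = SynthConfig(
        shape=shape, schedule=[(0, max(1, len(centers_um)))], diameter_um=diameter,
        noise_sigma=0.005, shot_scale=0.01, seed=seed,
    )
    stack, _ = render_frame(np.asarray(centers_um, float), cfg, diameter_um=diameter)
    return stack


def _filtered(stack):
    return ImageStack(dog_response(stack, DoGSpec(l_xy=4.0, dim="3D")), stack.spacing)


@pytest.mark.parametrize("method", METHOD_NAMES)
class TestMethodBattery:
    def test_blank_image_yields_no_regions(self, method, screened_params):
        blank = ImageStack(np.zeros((16, 48, 48)), SPACING)
        assert segment(method, blank, screened_params).n_labels == 0

    def test_single_nucleus_detected_accurately(self, method, screened_params):
        center = np.array([[15.0, 12.0, 12.0]])  # z, y, x um
        stack = _render_nuclei(center, shape=(30, 96, 96))
        vol = segment(method, _filtered(stack), screened_params)
        dets = region_centroids(vol)
        assert len(dets) == 1
        got = np.asarray(dets[0].centroid)  # x, y, z
        expected = center[0][::-1]
        assert np.linalg.norm(got - expected) < 0.5

    def test_two_distant_nuclei_both_found(self, method, screened_params):
        centers = np.array([[15.0, 8.0, 8.0], [15.0, 17.0, 17.0]])  # 12.7 um apart
        stack = _render_nuclei(centers)
        vol = segment(method, _filtered(stack), screened_params)
        dets = region_centroids(vol)
        assert len(dets) == 2
        tp, fp, fn, _ = mutual_nn_oracle(
            [d.centroid for d in dets], centers[:, ::-1], threshold=5.0
        )
        assert (tp, fp, fn) == (2, 0, 0)

    def test_foreground_restriction(self, method, easy_filtered, screened_params):
        """Positive labels lie inside the method's own foreground mask."""
        filtered, _ = easy_filtered
        vol = segment(method, filtered, screened_params)
        fg = vol.labels > 0
        if method in ("int", "locwat", "locreg"):
            mask = filtered.intensities > screened_params.intensity_threshold
        else:
            mask = local_threshold(filtered, screened_params.win, screened_params.offset)
        assert not (fg & ~mask).any()

    def test_determinism(self, method, easy_filtered, screened_params):
        filtered, _ = easy_filtered
        a = segment(method, filtered, screened_params).labels
        b = segment(method, filtered, screened_params).labels
        np.testing.assert_array_equal(a, b)


class TestMethodSpecifics:
    def test_hyb_alpha_zero_reduces_to_dst(self, easy_filtered, screened_params):
        filtered, _ = easy_filtered
        from dataclasses import replace
        p0 = replace(screened_params, alpha=0.0)
        hyb = segment_hyb(filtered, p0).labels
        dst = segment_dst(filtered, screened_params).labels
        np.testing.assert_array_equal(canonical_labels(hyb), canonical_labels(dst))

    def test_hyb_alpha_one_is_intensity_within_mask(self, easy_filtered, screened_params):
        filtered, _ = easy_filtered
        from dataclasses import replace
        p1 = replace(screened_params, alpha=1.0)
        hyb = segment_hyb(filtered, p1).labels
        mask = local_threshold(filtered, screened_params.win, screened_params.offset)
        expected = watershed_transform(
            -_rescale01(filtered.intensities), mask=mask, spacing=filtered.spacing
        )
        expected = size_filter(expected, screened_params.min_voxels).labels
        np.testing.assert_array_equal(canonical_labels(hyb), canonical_labels(expected))

    def test_locwat_region_count_equals_seed_count(self, easy_filtered, screened_params):
        from dataclasses import replace
        filtered, _ = easy_filtered
        p = replace(screened_params, min_voxels=0)
        maxima = find_local_maxima(
            filtered, screened_params.maxima_radius, screened_params.intensity_threshold
        )
        vol = segment_locwat(filtered, p)
        assert vol.n_labels == len(maxima)

    def test_locreg_regions_within_designated_distance(self, easy_filtered, screened_params):
        filtered, _ = easy_filtered
        vol = segment_locreg(filtered, screened_params)
        maxima = find_local_maxima(
            filtered, screened_params.maxima_radius, screened_params.intensity_threshold
        )
        steps = np.asarray(SPACING.zyx)
        seed_um = maxima * steps
        fg = np.argwhere(vol.labels > 0) * steps
        for v in fg:
            assert np.sqrt(((seed_um - v) ** 2).sum(axis=1)).min() <= (
                screened_params.region_radius + 1e-9
            )
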