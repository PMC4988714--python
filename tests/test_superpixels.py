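import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import measure

from lungseg.stackio import ImageStack, StackValidationError
from lungseg.superpixels import (
    ClusterCenter,
    PixelFeature,
    default_roi_rect,
    enforce_connectivity,
    extract_roi,
    gradient,
    gradient_map,
    grid_step,
    init_centers,
    pixel_distance,
    segment_stack,
)


class TestExtractRoi:
    def test_default_rect_512(self):
        stack = ImageStack(np.zeros((2, 512, 512)))
        roi = extract_roi(stack)
        assert (roi.width, roi.height) == (300, 360)
        assert roi.offset == (100, 60)

    def test_default_rect_scales_to_256(self):
        stack = ImageStack(np.zeros((1, 256, 256)))
        assert default_roi_rect(256, 256) == (50, 30, 200, 210)
        roi = extract_roi(stack)
        assert (roi.width, roi.height) == (150, 180)

    def test_full_frame_is_identity(self, rng):
        data = rng.normal(size=(2, 32, 32))
        roi = extract_roi(ImageStack(data), rect=(0, 0, 32, 32))
        np.testing.assert_array_equal(roi.data, data)

    def test_out_of_bounds_rect_rejected(self):
        stack = ImageStack(np.zeros((1, 32, 32)))
        with pytest.raises(StackValidationError):
            extract_roi(stack, rect=(0, 0, 64, 64))


class TestGridStep:
    @pytest.mark.parametrize("N,K,expected", [(100, 4, 5.0), (1024, 16, 8.0), (7, 7, 1.0)])
    def test_values(self, N, K, expected):
        assert grid_step(N, K) == pytest.approx(expected)

    def test_zero_k_rejected(self):
        with pytest.raises(StackValidationError):
            grid_step(100, 0)


class TestGradient:
    def test_constant_image_zero(self):
        img = np.full((8, 8), 3.0)
        assert gradient(img, 4, 4) == 0.0
        assert gradient_map(img).max() == 0.0

    def test_ramp_interior(self):
        img = np.tile(np.arange(8, dtype=float), (8, 1))  # V(x,y)=x
        assert gradient(img, 4, 4) == pytest.approx(2.0)

    def test_specific_neighbours(self):
        # V(x+1,y)=5, V(x-1,y)=1, V(x,y+1)=4, V(x,y-1)=1 -> sqrt(16+9)=5
        img = np.zeros((3, 3))
        img[1, 2], img[1, 0], img[2, 1], img[0, 1] = 5, 1, 4, 1
        assert gradient(img, 1, 1) == pytest.approx(5.0)

    def test_map_matches_pointwise(self, rng):
        img = rng.normal(size=(10, 12))
        gmap = gradient_map(img)
        for y in range(10):
            for x in range(12):
                assert gmap[y, x] == pytest.approx(gradient(img, x, y))


class TestInitCenters:
    def test_constant_slice_keeps_grid(self):
        centers = init_centers(np.zeros((20, 20)), S=10, n=3)
        assert len(centers) == 4
        assert sorted((c.x, c.y) for c in centers) == [
            (4.5, 4.5), (4.5, 14.5), (14.5, 4.5), (14.5, 14.5)
        ]

    def test_bright_ridge_repels_center(self):
        img = np.zeros((20, 20))
        img[:, 4] = 100.0  # ridge through the (4.5, ·) grid column
        centers = init_centers(img, S=10, n=3)
        gmap = gradient_map(img)
        for c in centers:
            px, py = int(round(c.x)), int(round(c.y))
            assert gmap[py, px] == 0.0  # moved off the ridge flank

    def test_centers_minimise_gradient_over_seed_window(self, rng):
        img = rng.normal(size=(24, 24)).cumsum(axis=1)  # smooth-ish
        gmap = gradient_map(img)
        centers = init_centers(img, S=8, n=3)
        # reconstruct the unperturbed grid positions (3×3 cells of 8 px)
        grid = [
            ((i + 0.5) * 8 - 0.5, (j + 0.5) * 8 - 0.5)
            for j in range(3)
            for i in range(3)
        ]
        for c, (gx, gy) in zip(centers, grid):
            px, py = int(round(gx)), int(round(gy))
            win = gmap[py - 1 : py + 2, px - 1 : px + 2]
            cx, cy = int(round(c.x)), int(round(c.y))
            assert gmap[cy, cx] == pytest.approx(win.min())

    def test_oversized_step_gives_global_minimum(self, rng):
        img = rng.normal(size=(8, 8))
        centers = init_centers(img, S=50, n=3)
        gmap = gradient_map(img)
        assert len(centers) == 1
        assert gmap[int(centers[0].y), int(centers[0].x)] == gmap.min()

    def test_even_window_rejected(self):
        with pytest.raises(StackValidationError):
            init_centers(np.zeros((8, 8)), S=4, n=2)


class TestPixelDistance:
    def test_identical_features_zero(self):
        p = PixelFeature(10, 0, 0, 5, 5, 0)
        c = ClusterCenter(10, 0, 0, 5, 5, 0, k=0)
        assert pixel_distance(p, c, delta=10) == 0.0

    def test_worked_example(self):
        # D_lab = 3, D_xy = 4, delta = 1 -> (3 + 4) / 2 = 3.5
        p = PixelFeature(3, 0, 0, 0, 4, 0)
        c = ClusterCenter(0, 0, 0, 0, 0, 0, k=0)
        assert np.hypot(p.l - c.l, 0) == 3  # independent D_lab check
        assert np.hypot(p.x - c.x, p.y - c.y) == 4  # independent D_xy check
        assert pixel_distance(p, c, delta=1) == pytest.approx(3.5)

    def test_large_delta_limit_vanishes(self):
        p = PixelFeature(0, 0, 0, 3, 4, 0)
        c = ClusterCenter(0, 0, 0, 0, 0, 0, k=0)
        values = [pixel_distance(p, c, delta=d) for d in (5, 10, 100, 1000)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(0.0, abs=1e-2)

    def test_nonpositive_delta_rejected(self):
        p = PixelFeature(0, 0, 0, 0, 0, 0)
        c = ClusterCenter(0, 0, 0, 0, 0, 0, k=0)
        with pytest.raises(StackValidationError):
            pixel_distance(p, c, delta=0)

    def test_cross_slice_rejected(self):
        p = PixelFeature(0, 0, 0, 0, 0, 1)
        c = ClusterCenter(0, 0, 0, 0, 0, 0, k=0)
        with pytest.raises(StackValidationError):
            pixel_distance(p, c, delta=1)


class TestSegmentStack:
    def test_constant_image_four_equal_superpixels(self):
        stack = ImageStack(np.zeros((1, 32, 32)))
        spmap = segment_stack(stack, K=4)
        assert spmap.iterations == [1]
        labels = spmap.labels[0]
        areas = np.bincount(labels.ravel())
        assert len(areas) == 4
        assert np.all(areas == 256)
        for lab in range(4):
            assert measure.label(labels == lab, connectivity=1).max() == 1

    def test_two_region_image_matches_nearest_center_oracle(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 100.0
        stack = ImageStack(img[None])
        spmap = segment_stack(stack, K=2)
        labels = spmap.labels[0]
        # brute-force oracle: nearest converged centre by the same distance
        feats = spmap.features
        delta = spmap.params["delta"]
        ys, xs = np.mgrid[0:16, 0:16]
        norm = (img - img.min()) * 100.0 / np.ptp(img)
        best = np.full((16, 16), -1)
        bestd = np.full((16, 16), np.inf)
        for k in range(len(feats)):
            d_lab = np.abs(norm - feats[k, 0])
            d_xy = np.hypot(xs - feats[k, 3], ys - feats[k, 4])
            ds = (d_lab + delta * d_xy) / (1 + delta**2)
            upd = ds < bestd
            bestd[upd] = ds[upd]
            best[upd] = k
        disagree = labels != best
        # disagreement confined to a 1-px band around the region boundary
        assert np.all(np.abs(xs[disagree] - 7.5) <= 1.5)

    def test_partition_and_feature_consistency(self, rng):
        data = rng.normal(size=(2, 24, 24)).cumsum(axis=2)
        stack = ImageStack(data)
        spmap = segment_stack(stack, K=9)
        norm = (data - data.min()) * 100.0 / np.ptp(data)
        seen = set()
        for z, labels in enumerate(spmap.labels):
            ids = np.unique(labels)
            assert labels.size == 24 * 24  # every pixel labelled once
            for i in ids:
                assert i not in seen  # globally unique ids
                seen.add(i)
                mask = labels == i
                row = spmap.features[i]
                assert row[0] == pytest.approx(norm[z][mask].mean(), abs=1e-6)
                ys, xs = np.nonzero(mask)
                assert row[3] == pytest.approx(xs.mean(), abs=1e-6)
                assert row[4] == pytest.approx(ys.mean(), abs=1e-6)
                assert row[5] == z
        assert len(seen) == spmap.n_superpixels

    def test_identical_slices_converge_faster(self, rng):
        sl = rng.normal(size=(20, 20)).cumsum(axis=0)
        stack = ImageStack(np.repeat(sl[None], 5, axis=0))
        spmap = segment_stack(stack, K=9)
        assert all(it <= spmap.iterations[0] for it in spmap.iterations[1:])

    def test_invalid_parameters_rejected(self):
        stack = ImageStack(np.zeros((1, 16, 16)))
        with pytest.raises(StackValidationError):
            segment_stack(stack, K=4, delta=0)
        with pytest.raises(StackValidationError):
            segment_stack(stack, K=0)


class TestEnforceConnectivity:
    def test_connected_map_unchanged(self):
        labels = np.repeat(np.arange(4).reshape(2, 2), 3, axis=0).repeat(3, axis=1)
        np.testing.assert_array_equal(enforce_connectivity(labels, S=3), labels)

    def test_small_orphan_absorbed(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[:, 3:] = 1
        labels[0, 0] = 1  # 1-px orphan of label 1 inside label 0
        fixed = enforce_connectivity(labels, S=3)
        assert fixed[0, 0] == 0
        assert measure.label(fixed == 1, connectivity=1).max() == 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_maps_become_connected_without_new_labels(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 4, size=(8, 8))
        fixed = enforce_connectivity(labels, S=3)
        assert set(np.unique(fixed)) <= set(np.unique(labels))
        for lab in np.unique(fixed):
            assert measure.label(fixed == lab, connectivity=1).max() == 1
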