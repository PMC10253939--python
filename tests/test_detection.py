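import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linespark import (
    DetectionParams,
    LineScanImage,
    ScanSimConfig,
    binarize,
    centroid,
    detect,
    erode,
    localize,
    normalize_time,
    simulate_linescan,
    smooth,
)
from linespark.detection import BinaryMask, NormalizedScan

from _oracles import (
    brute_boxcar,
    brute_centroid,
    brute_components,
    brute_erode_cross,
    brute_normalize,
)
from conftest import SIM_PARAMS


class TestSmooth:
    def test_constant_image_invariant(self):
        img = LineScanImage(np.full((16, 64), 42.0), 0.1, 0.002)
        out = smooth(img, 5, 3)
        np.testing.assert_allclose(out.pixels, 42.0)

    def test_impulse_spreads_to_box(self):
        px = np.zeros((17, 65))
        px[8, 32] = 9.0
        img = LineScanImage(px, 0.1, 0.002)
        out = smooth(img, 3, 3)
        np.testing.assert_allclose(out.pixels[7:10, 31:34], 1.0, atol=1e-12)
        assert out.pixels[6, 32] == 0.0 and out.pixels[8, 35] == 0.0

    def test_even_or_nonpositive_cutoff_rejected(self, small_image):
        with pytest.raises(ValueError):
            smooth(small_image, 2, 3)
        with pytest.raises(ValueError):
            smooth(small_image, 3, 0)

    @pytest.mark.parametrize("cutoffs", [(3, 1), (1, 3), (3, 3), (5, 7)])
    def test_matches_brute_force(self, small_image, cutoffs):
        out = smooth(small_image, *cutoffs)
        expected = brute_boxcar(small_image.pixels, *cutoffs)
        np.testing.assert_allclose(out.pixels, expected, atol=1e-9)


class TestNormalizeTime:
    def test_constant_input_is_exactly_one(self):
        img = LineScanImage(np.full((8, 64), 17.0), 0.1, 0.002)
        norm = normalize_time(img, 5)
        np.testing.assert_array_equal(norm.values, 1.0)
        assert norm.global_sd == 0.0

    def test_isolated_peak_over_flat_background(self):
        # a row of ones with a single 6 at the centre: the peak divides the
        # mean of its ten flanking ones, giving exactly 6
        px = np.ones((8, 64))
        px[:, 32] = 6.0
        img = LineScanImage(px, 0.1, 0.002)
        norm = normalize_time(img, 5)
        assert norm.values[0, 32] == pytest.approx(6.0)

    def test_too_short_scan_rejected(self):
        img = LineScanImage(np.ones((8, 32)), 0.1, 0.002)
        with pytest.raises(ValueError, match="too short"):
            normalize_time(img, 16)

    def test_zero_pixels_floored_with_warning(self):
        px = np.ones((8, 64))
        px[3, 10] = 0.0
        img = LineScanImage(px, 0.1, 0.002)
        with pytest.warns(RuntimeWarning, match="flooring"):
            norm = normalize_time(img, 5)
        assert np.all(np.isfinite(norm.values))

    @pytest.mark.parametrize("half_window", [1, 3, 5, 11])
    def test_matches_brute_force_including_edges(self, half_window, rng):
        pixels = rng.uniform(50.0, 150.0, size=(8, 64))
        img = LineScanImage(pixels, 0.1, 0.002)
        norm = normalize_time(img, half_window)
        np.testing.assert_allclose(
            norm.values, brute_normalize(pixels, half_window), atol=1e-12
        )

    def test_grand_mean_near_one(self):
        # fluorescence-like noise (up to ~20% relative SD); the reciprocal
        # bias of the running mean stays well inside 0.02 at that level
        rng = np.random.default_rng(11)
        for _ in range(10):
            baseline = rng.uniform(50, 200)
            noise = baseline * rng.uniform(0.02, 0.2)
            pixels = np.clip(
                rng.normal(baseline, noise, size=(12, 96)), 1e-3, None
            )
            norm = normalize_time(LineScanImage(pixels, 0.1, 0.002), 5)
            assert abs(norm.values.mean() - 1.0) < 0.02
            assert norm.global_sd > 0


class TestBinarize:
    def make_norm(self, values):
        return NormalizedScan(values, float(np.std(values)), 0.1, 0.002)

    def test_constant_input_empty_mask_with_warning(self):
        norm = self.make_norm(np.ones((8, 32)))
        with pytest.warns(RuntimeWarning, match="zero standard deviation"):
            mask = binarize(norm, 1.5)
        assert mask.bits.sum() == 0

    def test_exceeding_pixel_selected(self, rng):
        values = 1.0 + rng.normal(0, 0.01, size=(16, 64))
        norm = self.make_norm(values)
        spike = self.make_norm(values.copy())
        spike.values[5, 20] = 1.0 + 5 * norm.global_sd
        spike.global_sd = float(np.std(spike.values))
        mask = binarize(spike, 1.5)
        assert mask.bits[5, 20] == 1

    def test_threshold_subset_property(self, rng):
        values = 1.0 + rng.normal(0, 0.05, size=(16, 64))
        norm = self.make_norm(values)
        hi = binarize(norm, 1.5).bits
        lo = binarize(norm, 0.5).bits
        assert np.all(hi <= lo)

    @settings(max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n1=st.floats(0.1, 1.0),
        n2=st.floats(1.0, 3.0),
    )
    def test_threshold_monotonicity_survives_erosion(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        values = 1.0 + rng.normal(0, 0.05, size=(12, 48))
        norm = self.make_norm(values)
        lo = erode(binarize(norm, min(n1, n2)), 1)
        hi = erode(binarize(norm, max(n1, n2)), 1)
        assert np.all(hi.bits <= lo.bits)


class TestErode:
    def test_isolated_pixel_removed(self):
        bits = np.zeros((8, 32), dtype=np.uint8)
        bits[4, 16] = 1
        out = erode(BinaryMask(bits, 1.0), 1)
        assert out.bits.sum() == 0

    def test_block_shrinks_by_one(self):
        bits = np.zeros((9, 33), dtype=np.uint8)
        bits[2:7, 14:19] = 1
        out = erode(BinaryMask(bits, 1.0), 1)
        expected = np.zeros_like(bits)
        expected[3:6, 15:18] = 1
        np.testing.assert_array_equal(out.bits, expected)

    def test_zero_iterations_is_identity(self, rng):
        bits = (rng.random((8, 32)) < 0.5).astype(np.uint8)
        out = erode(BinaryMask(bits, 1.0), 0)
        np.testing.assert_array_equal(out.bits, bits)

    @pytest.mark.parametrize("iterations", [1, 2])
    def test_matches_brute_force(self, rng, iterations):
        bits = (rng.random((16, 48)) < 0.6).astype(np.uint8)
        out = erode(BinaryMask(bits, 1.0), iterations)
        np.testing.assert_array_equal(out.bits, brute_erode_cross(bits, iterations))


class TestLocalize:
    def test_empty_mask(self):
        mask = BinaryMask(np.zeros((8, 32), dtype=np.uint8), 1.0)
        assert localize(mask, 1) == []

    def test_min_area_filters_small_blob(self):
        bits = np.zeros((16, 64), dtype=np.uint8)
        bits[2:5, 10:14] = 1  # 12 px
        bits[10:11, 40:43] = 1  # 3 px
        cands = localize(BinaryMask(bits, 1.0), 10)
        assert len(cands) == 1
        assert cands[0].area_px == 12

    def test_ordering_by_time_then_space(self):
        bits = np.zeros((16, 64), dtype=np.uint8)
        bits[10:13, 5:10] = 1  # earlier in time, lower block
        bits[1:4, 5:10] = 1  # same j_min, smaller i_min -> first
        bits[5:8, 30:35] = 1  # later in time
        cands = localize(BinaryMask(bits, 1.0), 1)
        assert [c.bbox[:3:2] for c in cands] == [(1, 5), (10, 5), (5, 30)]

    def test_matches_flood_fill_and_hull_contains_members(self, rng):
        from scipy.spatial import ConvexHull, QhullError

        for trial in range(10):
            bits = (np.random.default_rng(trial).random((16, 48)) < 0.35).astype(
                np.uint8
            )
            cands = localize(BinaryMask(bits, 1.0), 3)
            expected = brute_components(bits, 3)
            got = [frozenset(map(tuple, c.pixels)) for c in cands]
            assert sorted(map(sorted, got)) == sorted(map(sorted, expected))
            for cand in cands:
                # every member pixel inside the hull of the member pixels
                try:
                    hull = ConvexHull(cand.pixels.astype(float))
                except QhullError:
                    continue  # collinear component: hull is the segment
                eq = hull.equations
                pts = cand.pixels.astype(float)
                assert np.all(pts @ eq[:, :2].T + eq[:, 2] <= 1e-9)
                assert set(map(tuple, np.array(cand.hull_vertices))) <= set(
                    map(tuple, cand.pixels)
                )


class TestCentroid:
    def make_norm(self, shape=(16, 64)):
        return NormalizedScan(np.ones(shape), 0.0, 0.1, 0.002)

    def candidate_from(self, pixels):
        from linespark.detection import SparkCandidate

        coords = np.array(pixels)
        return SparkCandidate(
            pixels=coords,
            hull_vertices=[],
            area_px=len(coords),
            bbox=(
                coords[:, 0].min(),
                coords[:, 0].max(),
                coords[:, 1].min(),
                coords[:, 1].max(),
            ),
            threshold_n=1.0,
        )

    def test_symmetric_blob_gives_geometric_centre(self):
        norm = self.make_norm()
        norm.values[4:7, 10:13] = 2.0
        cand = self.candidate_from(
            [(i, j) for i in range(4, 7) for j in range(10, 13)]
        )
        assert centroid(cand, norm) == pytest.approx((5.0, 11.0))

    def test_weighted_mean_arithmetic(self):
        norm = self.make_norm()
        norm.values[3, 10] = 4.0  # weight 3
        norm.values[3, 20] = 2.0  # weight 1
        cand = self.candidate_from([(3, 10), (3, 20)])
        ci, cj = centroid(cand, norm)
        assert (ci, cj) == pytest.approx((3.0, 12.5))

    def test_zero_weights_fall_back_to_unweighted_mean(self):
        norm = self.make_norm()  # all values 1 -> all weights 0
        cand = self.candidate_from([(2, 5), (4, 9)])
        assert centroid(cand, norm) == pytest.approx((3.0, 7.0))

    def test_matches_brute_force(self, rng):
        norm = self.make_norm()
        norm.values += rng.normal(0, 0.3, size=norm.values.shape)
        coords = rng.integers(0, [16, 64], size=(20, 2))
        cand = self.candidate_from([tuple(c) for c in coords])
        assert centroid(cand, norm) == pytest.approx(
            brute_centroid(cand.pixels, norm.values)
        )
        ci, cj = centroid(cand, norm)
        i0, i1, j0, j1 = cand.bbox
        assert i0 <= ci <= i1 and j0 <= cj <= j1


class TestDetect:
    def test_pure_noise_has_almost_no_candidates(self):
        # default parameters at the strictest threshold: isolated noise
        # crossings must be eliminated by erosion plus the area criterion
        total_px = 0
        total_candidates = 0
        for seed in range(20):
            config = ScanSimConfig(
                n_space=64, n_time=2000, n_sparks=0, seed=seed, noise_sd=50.0
            )
            image, _ = simulate_linescan(config)
            result = detect(image, DetectionParams(threshold_n=1.5))
            total_px += image.pixels.size
            total_candidates += len(result.candidates)
        assert total_candidates <= total_px / 10_000

    def test_five_sparks_recovered_with_accurate_centroids(self, sparky_scan):
        image, truth = sparky_scan
        result = detect(image, SIM_PARAMS)
        assert len(result.candidates) == 5
        got = sorted(
            (
                (c.centroid[1] + 0.5) * image.line_period,
                (c.centroid[0] + 0.5) * image.pixel_size,
            )
            for c in result.candidates
        )
        want = sorted((t.t_peak_s, t.x_center_um) for t in truth)
        for (t_got, x_got), (t_want, x_want) in zip(got, want):
            assert abs(x_got - x_want) < 0.3  # um
            assert abs(t_got - t_want) < 0.05  # s

    def test_detection_is_deterministic(self, sparky_scan):
        image, _ = sparky_scan
        r1 = detect(image, SIM_PARAMS)
        r2 = detect(image, SIM_PARAMS)
        assert len(r1) == len(r2)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.pixels, b.pixels)
            assert a.centroid == b.centroid
        np.testing.assert_array_equal(r1.normalized.values, r2.normalized.values)

    def test_stages_preserve_shape(self, small_image):
        result = detect(small_image, DetectionParams(half_window=5))
        assert result.normalized.values.shape == small_image.pixels.shape
        assert result.mask.bits.shape == small_image.pixels.shape
        assert result.eroded.bits.shape == small_image.pixels.shape
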