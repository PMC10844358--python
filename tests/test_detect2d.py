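"""Phase-I detection: binarization, closing, void extraction, superimposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lumenmetry import (
    Calibration,
    DetectionConfig,
    FusedSlice,
    binarize_slice,
    close_mask,
    detect_slice,
    extract_voids,
    iteration_radii,
    superimpose,
)
from lumenmetry.detect2d import BinarySlice

from conftest import annulus_slice
from oracles import (
    brute_close,
    exhaustive_otsu_classify,
    oracle_void_components,
    random_blob_mask,
)

CAL1 = Calibration(1.0, 5.0)


class TestIterationRadii:
    def test_defaults_follow_six_start_five_increment_eight_steps(self):
        assert iteration_radii(DetectionConfig()) == [6, 11, 16, 21, 26, 31, 36, 41]

    @pytest.mark.parametrize("kwargs,expected", [
        ({"n_iter": 1}, [6.0]),
        ({"r0": 4.0, "dr": 2.0, "n_iter": 3}, [4.0, 6.0, 8.0]),
    ])
    def test_arithmetic_progression(self, kwargs, expected):
        assert iteration_radii(DetectionConfig(**kwargs)) == expected

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DetectionConfig(r0=0.0)
        with pytest.raises(ValueError):
            DetectionConfig(n_iter=0)


class TestBinarize:
    def test_blank_and_constant_slices_are_all_background(self):
        for value in (0.0, 0.5):
            fused = FusedSlice(np.full((16, 16), value), 0)
            assert not binarize_slice(fused, DetectionConfig()).mask.any()

    def test_two_valued_image_splits_exactly_without_smoothing(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((32, 32)) < 0.4, 0.8, 0.1)
        cfg = DetectionConfig(smoothing_sigma=0.0)
        out = binarize_slice(FusedSlice(img, 0), cfg).mask
        np.testing.assert_array_equal(out, img == 0.8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_between_class_variance_oracle(self, seed):
        # two well-separated intensity clusters with random proportions: the
        # optimal cut must land in the central gap for both the histogram
        # implementation and the exhaustive midpoint search
        rng = np.random.default_rng(seed)
        levels = np.array([0.05, 0.15, 0.7, 0.9])
        weights = np.concatenate([
            rng.dirichlet([2, 2]) * rng.uniform(0.3, 0.7),
            rng.dirichlet([2, 2]),
        ])
        weights[2:] *= (1 - weights[:2].sum()) / weights[2:].sum()
        img = rng.choice(levels, p=weights / weights.sum(), size=(24, 24))
        cfg = DetectionConfig(smoothing_sigma=0.0)
        out = binarize_slice(FusedSlice(img, 0), cfg).mask
        np.testing.assert_array_equal(out, exhaustive_otsu_classify(img))

    def test_fixed_threshold_method(self):
        img = np.linspace(0, 1, 25).reshape(5, 5)
        cfg = DetectionConfig(binarize_method="fixed", fixed_threshold=0.6,
                              smoothing_sigma=0.0)
        out = binarize_slice(FusedSlice(img, 0), cfg).mask
        np.testing.assert_array_equal(out, img > 0.6)


class TestCloseMask:
    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(1)
        m = BinarySlice(rng.random((20, 20)) > 0.5, 0)
        np.testing.assert_array_equal(close_mask(m, 0.0, CAL1).mask, m.mask)

    def test_ring_break_sealed_by_large_disk(self):
        ring = annulus_slice(size=40, center=(20, 20), r_inner=8, r_outer=12,
                             gap_px=1.0).raster.astype(bool)
        closed = close_mask(BinarySlice(ring, 0), 4.0, CAL1).mask
        comps = oracle_void_components(closed, min_area_px=1)
        assert len(comps) == 1  # interior hole enclosed again

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_dilation_erosion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_blob_mask(rng, shape=(48, 48))
        r = int(rng.integers(1, 6))
        got = close_mask(BinarySlice(mask, 0), float(r), CAL1).mask
        np.testing.assert_array_equal(got, brute_close(mask, r))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), r=st.floats(0.0, 6.0))
    def test_extensive_and_idempotent(self, seed, r):
        rng = np.random.default_rng(seed)
        m = BinarySlice(random_blob_mask(rng, shape=(32, 32)), 0)
        once = close_mask(m, r, CAL1)
        assert np.all(once.mask >= m.mask)  # extensivity
        twice = close_mask(once, r, CAL1)
        np.testing.assert_array_equal(twice.mask, once.mask)  # idempotence


class TestExtractVoids:
    def _solid_disk_with_holes(self, holes):
        yy, xx = np.mgrid[0:50, 0:50].astype(float)
        disk = (yy - 25) ** 2 + (xx - 25) ** 2 <= 20 ** 2
        for cy, cx, r in holes:
            disk &= (yy - cy) ** 2 + (xx - cx) ** 2 > r ** 2
        return disk

    def test_single_hole_yields_one_candidate_with_flood_fill_area(self):
        mask = self._solid_disk_with_holes([(25, 25, 5)])
        cands = extract_voids(BinarySlice(mask, 0), DetectionConfig(min_area_um2=1), CAL1)
        comps = oracle_void_components(mask, min_area_px=1)
        assert len(cands) == 1 and len(comps) == 1
        assert cands[0].area_um2 == len(comps[0])
        assert {tuple(p) for p in np.argwhere(cands[0].mask)} == set(comps[0])

    def test_two_holes_yield_two_candidates(self):
        mask = self._solid_disk_with_holes([(18, 18, 4), (32, 32, 5)])
        cands = extract_voids(BinarySlice(mask, 0), DetectionConfig(min_area_um2=1), CAL1)
        assert len(cands) == 2

    def test_all_foreground_slice_has_no_candidates(self):
        mask = np.ones((20, 20), dtype=bool)
        assert extract_voids(BinarySlice(mask, 0), DetectionConfig(), CAL1) == []

    def test_background_is_never_returned(self):
        mask = self._solid_disk_with_holes([(25, 25, 5)])
        cands = extract_voids(BinarySlice(mask, 0), DetectionConfig(min_area_um2=1), CAL1)
        border_void = ~mask
        border_void[1:-1, 1:-1] = False
        for c in cands:
            assert not (c.mask & border_void).any()

    def test_min_area_filter_drops_small_voids(self):
        mask = self._solid_disk_with_holes([(25, 25, 6), (14, 25, 1.2)])
        cfg = DetectionConfig(min_area_um2=20.0)
        cands = extract_voids(BinarySlice(mask, 0), cfg, CAL1)
        assert len(cands) == 1
        assert cands[0].area_um2 >= 20.0

    def test_border_filter_drops_border_touching_voids(self):
        mask = np.ones((20, 20), dtype=bool)
        mask[0:3, 5:8] = False   # void touching the top border
        mask[10:13, 5:8] = False  # interior void
        mask[17:, 0:2] = False    # largest background stand-in
        mask[15:, 15:] = False
        cfg = DetectionConfig(min_area_um2=1.0, border_filter=True)
        cands = extract_voids(BinarySlice(mask, 0), cfg, CAL1)
        for c in cands:
            y0, x0, y1, x1 = c.bbox
            assert y0 > 0 and x0 > 0 and y1 < 20 and x1 < 20


class TestSuperimpose:
    def _cand(self, pixels, z=0, it=1, label=1):
        from conftest import make_candidate

        mask = np.zeros((30, 30), dtype=bool)
        for y, x in pixels:
            mask[y, x] = True
        return make_candidate(mask, z=z, first_iter=it, label=label)

    def test_overlapping_detections_keep_largest_form(self):
        big = self._cand([(y, x) for y in range(5, 17) for x in range(5, 15)], it=1)
        small = self._cand([(y, x) for y in range(6, 16) for x in range(6, 14)], it=2)
        assert big.n_pixels == 120 and small.n_pixels == 80
        out = superimpose([[big], [small]])
        assert len(out) == 1
        assert out[0] is big

    def test_disjoint_candidates_all_retained(self):
        a = self._cand([(2, 2), (2, 3)], it=1, label=1)
        b = self._cand([(20, 20), (20, 21)], it=2, label=2)
        out = superimpose([[a], [b]])
        assert len(out) == 2

    def test_empty_input_gives_empty_output(self):
        assert superimpose([]) == []
        assert superimpose([[], []]) == []

    def test_output_masks_are_inputs_verbatim_and_no_larger(self):
        rng = np.random.default_rng(3)
        groups = []
        all_cands = []
        for it in (1, 2, 3):
            cands = [
                self._cand(
                    [(y, x)
                     for y in range(int(rng.integers(0, 10)), int(rng.integers(12, 25)))
                     for x in range(int(rng.integers(0, 10)), int(rng.integers(12, 25)))],
                    it=it, label=k)
                for k in range(2)
            ]
            groups.append(cands)
            all_cands.extend(cands)
        out = superimpose(groups)
        assert len(out) <= len(all_cands)
        for rep in out:
            assert any(rep is c for c in all_cands)


class TestDetectSlice:
    def test_blank_slice_detects_nothing(self, cal2):
        fused = FusedSlice(np.zeros((64, 64)), 0)
        assert detect_slice(fused, DetectionConfig(), cal2) == []

    def test_gap_free_void_found_at_first_iteration_with_accurate_area(self, cal2):
        fused = annulus_slice(size=64, r_inner=10, r_outer=16)
        cfg = DetectionConfig(smoothing_sigma=0.0)
        cands = detect_slice(fused, cfg, cal2)
        assert len(cands) == 1
        assert cands[0].first_iter == 1
        true_area_um2 = np.pi * (10 * cal2.pixel_size_xy) ** 2
        assert abs(cands[0].area_um2 - true_area_um2) / true_area_um2 < 0.1

    def test_gapped_void_appears_exactly_once(self, cal2):
        # 8 um gap = 4 px at 2 um/px; sealed by the first disk (12 um diameter)
        fused = annulus_slice(size=64, r_inner=10, r_outer=16, gap_px=4.0)
        cfg = DetectionConfig(smoothing_sigma=0.0)
        cands = detect_slice(fused, cfg, cal2)
        assert len(cands) == 1
        # the brute-force oracle also finds it at some scheduled radius
        found = [
            len(oracle_void_components(
                brute_close(fused.raster.astype(bool), cal2.um_to_px(r)),
                min_area_px=7,
            )) >= 1
            for r in iteration_radii(cfg)
        ]
        assert any(found)

    def test_detected_area_nonincreasing_with_disk_radius(self, cal2):
        from lumenmetry import binarize_slice

        fused = annulus_slice(size=64, r_inner=10, r_outer=16)
        cfg = DetectionConfig(smoothing_sigma=0.0)
        binary = binarize_slice(fused, cfg)
        areas = []
        for it, r in enumerate(iteration_radii(cfg), start=1):
            closed = close_mask(binary, r, cal2, cfg)
            cands = extract_voids(closed, cfg, cal2, iteration=it)
            if cands:
                areas.append(max(c.area_um2 for c in cands))
        assert areas == sorted(areas, reverse=True)
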