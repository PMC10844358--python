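"""Grouping, point clouds and alpha-shape volumetry."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from lumenmetry import (
    AlphaShape3D,
    Calibration,
    build_point_cloud,
    group_lumens,
    reconstruct,
    summarize,
)

from conftest import digitized_ball_candidates, make_candidate


def _box_candidate(z, y0, x0, side=6, shape=(40, 40), label=1):
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y0 + side, x0:x0 + side] = True
    return make_candidate(mask, z=z, label=label)


class TestGrouping:
    def test_contiguous_overlapping_slices_form_one_group(self):
        cands = [_box_candidate(z, 10, 10) for z in (2, 3, 4)]
        groups = group_lumens(cands)
        assert len(groups) == 1
        assert len(groups[0].members) == 3

    def test_z_gap_splits_into_two_groups(self):
        cands = [_box_candidate(z, 10, 10) for z in (2, 3, 5, 6)]
        groups = group_lumens(cands, max_gap=0)
        assert len(groups) == 2
        assert [g.z_levels for g in groups] == [[2, 3], [5, 6]]

    def test_laterally_disjoint_lumens_stay_separate(self):
        a = [_box_candidate(z, 5, 5, label=1) for z in (2, 3)]
        b = [_box_candidate(z, 25, 25, label=2) for z in (2, 3)]
        assert len(group_lumens(a + b)) == 2

    def test_max_gap_one_bridges_single_missing_slice(self):
        cands = [_box_candidate(z, 10, 10) for z in (2, 3, 5, 6)]
        assert len(group_lumens(cands, max_gap=1)) == 1

    def test_grouping_is_a_partition(self):
        rng = np.random.default_rng(0)
        cands = []
        for k in range(30):
            z = int(rng.integers(0, 8))
            y0 = int(rng.integers(0, 30))
            x0 = int(rng.integers(0, 30))
            cands.append(_box_candidate(z, y0, x0, side=5, label=k))
        for max_gap in (0, 1, 2):
            groups = group_lumens(cands, max_gap=max_gap)
            seen = [m.candidate_id for g in groups for m in g.members]
            assert sorted(seen) == sorted(c.candidate_id for c in cands)

    def test_increasing_max_gap_never_increases_group_count(self):
        rng = np.random.default_rng(1)
        cands = [
            _box_candidate(int(rng.integers(0, 10)), int(rng.integers(0, 30)),
                           int(rng.integers(0, 30)), side=5, label=k)
            for k in range(25)
        ]
        counts = [len(group_lumens(cands, max_gap=g)) for g in range(4)]
        assert counts == sorted(counts, reverse=True)


class TestPointCloud:
    def test_square_mask_contributes_exposed_edge_midpoints(self, cal1):
        mask = np.zeros((20, 20), dtype=bool)
        mask[8:11, 8:11] = True  # 3x3 square: 12 exposed edges
        g = group_lumens([make_candidate(mask, z=2)])[0]
        cloud = build_point_cloud(g, cal1)
        # 12 midpoints at the section plane plus both half-slab end caps
        assert len(cloud) == 36
        z_vals = np.unique(cloud[:, 0])
        np.testing.assert_allclose(z_vals, [3.0, 4.0, 5.0])

    def test_two_members_give_union_of_clouds(self, cal1):
        m1 = np.zeros((20, 20), dtype=bool)
        m1[5:8, 5:8] = True
        m2 = np.zeros((20, 20), dtype=bool)
        m2[5:8, 5:8] = True
        g = group_lumens([make_candidate(m1, z=0), make_candidate(m2, z=1)])[0]
        cloud = build_point_cloud(g, cal1)
        # planes at z = -1, 0 (first member) and 2, 3 (last): 12 midpoints each
        assert len(cloud) == 48

    def test_subsampling_is_deterministic(self, cal1):
        mask = np.zeros((200, 200), dtype=bool)
        yy, xx = np.mgrid[0:200, 0:200]
        mask[(yy - 100) ** 2 + (xx - 100) ** 2 <= 90 ** 2] = True
        g = group_lumens([make_candidate(mask, z=0)])[0]
        a = build_point_cloud(g, cal1, max_points=500, seed=4)
        b = build_point_cloud(g, cal1, max_points=500, seed=4)
        np.testing.assert_array_equal(a, b)
        assert len(a) == 500


class TestReconstruct:
    def test_single_slice_lumen_uses_extrusion_convention(self):
        cal = Calibration(1.0, 5.0)
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:20, 10:20] = True  # area 100 um^2
        g = group_lumens([make_candidate(mask)])[0]
        lum = reconstruct(g, cal)
        assert lum.method == "extrusion"
        assert lum.volume_um3 == pytest.approx(500.0)
        # 2 * area + perimeter * z_step with 36 exposed boundary pixels
        assert lum.surface_area_um2 == pytest.approx(2 * 100 + 36 * 5.0)

    def test_digitized_ball_volume_within_ten_percent(self, cal1):
        members = digitized_ball_candidates(20.0, cal1)
        g = group_lumens(members)[0]
        lum = reconstruct(g, cal1)
        true = 4.0 / 3.0 * np.pi * 20.0 ** 3
        assert lum.method == "alpha"
        assert abs(lum.volume_um3 - true) / true < 0.10
        assert lum.surface_area_um2 > 0

    def test_vertical_cylinder_close_to_convex_hull_volume(self):
        cal = Calibration(1.0, 5.0)
        yy, xx = np.mgrid[0:40, 0:40].astype(float)
        mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15 ** 2
        members = [make_candidate(mask, z=z) for z in range(5)]
        g = group_lumens(members)[0]
        lum = reconstruct(g, cal)
        hull = ConvexHull(build_point_cloud(g, cal))
        assert abs(lum.volume_um3 - hull.volume) / hull.volume < 0.15

    def test_volume_scales_cubically_with_calibration(self):
        base = Calibration(1.0, 2.0)
        scaled = Calibration(2.0, 4.0)
        members = digitized_ball_candidates(12.0, base, size=40)
        g = group_lumens(members)[0]
        v1 = reconstruct(g, base).volume_um3
        v2 = reconstruct(g, scaled).volume_um3
        a1 = reconstruct(g, base).surface_area_um2
        a2 = reconstruct(g, scaled).surface_area_um2
        assert v2 == pytest.approx(8.0 * v1, rel=1e-6)
        assert a2 == pytest.approx(4.0 * a1, rel=1e-6)

    def test_alpha_volume_monotone_and_bounded_by_hull(self, cal1):
        members = digitized_ball_candidates(10.0, cal1, size=40)
        g = group_lumens(members)[0]
        cloud = build_point_cloud(g, cal1)
        hull_vol = ConvexHull(cloud).volume
        vols = [AlphaShape3D(cloud, alpha=a).volume for a in (2.0, 5.0, 10.0, 50.0)]
        assert vols == sorted(vols)
        assert vols[-1] <= hull_vol * (1 + 1e-9)

    def test_degenerate_multislice_group_falls_back_to_extrusion(
        self, cal1, monkeypatch, caplog
    ):
        import lumenmetry.reconstruct3d as r3d

        def _raise(*args, **kwargs):
            raise ValueError("all tetrahedra degenerate")

        monkeypatch.setattr(r3d, "AlphaShape3D", _raise)
        m = np.zeros((10, 10), dtype=bool)
        m[4, 4] = True
        g = group_lumens([make_candidate(m, z=0), make_candidate(m, z=1)])[0]
        with caplog.at_level("WARNING"):
            lum = reconstruct(g, cal1)
        assert lum.method == "extrusion"
        assert lum.volume_um3 == pytest.approx(2 * 1.0 * 2.0)
        assert any("falling back" in r.message for r in caplog.records)


class TestSummarize:
    def test_empty_report(self):
        rep = summarize("s1", [])
        assert rep.lumen_count == 0
        assert rep.total_volume_um3 == 0.0

    def test_counts_and_totals(self, cal1):
        members = digitized_ball_candidates(8.0, cal1, size=30)
        g = group_lumens(members)[0]
        lum = reconstruct(g, cal1)
        rep = summarize("s1", [lum, lum])
        assert rep.lumen_count == 2
        assert rep.total_volume_um3 == pytest.approx(2 * lum.volume_um3)

    def test_order_invariance(self, cal1):
        members = digitized_ball_candidates(8.0, cal1, size=30)
        g = group_lumens(members)[0]
        a = reconstruct(g, cal1, alpha=5.0)
        b = reconstruct(g, cal1, alpha=50.0)
        assert summarize("s", [a, b]).total_volume_um3 == pytest.approx(
            summarize("s", [b, a]).total_volume_um3
        )
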