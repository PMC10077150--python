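"""Morphometry operators against analytic and brute-force oracles."""

import numpy as np
import pytest

import retmorph as rm
from retmorph.mask import BinaryMask

from conftest import brute_force_min_rect_long_side, make_convex_blob


def sierpinski(depth):
    g = np.array([[True]])
    for _ in range(depth):
        z = np.zeros_like(g)
        g = np.block([[g, g], [g, z]])
    return g


class TestDiscGeometry:
    def test_axis_aligned_rectangle_measures_its_long_side(self):
        g = np.zeros((50, 50), dtype=bool)
        g[10:20, 15:35] = True  # 10 rows x 20 cols
        d = rm.disc_geometry(BinaryMask(g))
        assert d.diameter_px == pytest.approx(20.0)
        assert d.center == pytest.approx((14.5, 24.5))

    def test_filled_circle_measures_its_diameter(self):
        rr, cc = np.ogrid[:200, :200]
        g = (rr - 100) ** 2 + (cc - 100) ** 2 <= 55 ** 2
        d = rm.disc_geometry(BinaryMask(g))
        assert d.diameter_px == pytest.approx(110, abs=1)

    def test_rotated_rectangle_recovers_true_long_side(self):
        th = np.radians(30)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = np.stack(np.meshgrid(np.arange(80), np.arange(80),
                                   indexing="ij"), -1).reshape(-1, 2) - 40
        # sub-pixel offset: a rectangle whose boundary passes exactly
        # through pixel centers is a degenerate lattice alignment
        loc = (pts - np.array([0.13, 0.37])) @ R
        inside = (abs(loc[:, 0]) <= 6) & (abs(loc[:, 1]) <= 15)
        g = np.zeros((80, 80), dtype=bool)
        g[(pts[:, 0] + 40)[inside], (pts[:, 1] + 40)[inside]] = True
        d = rm.disc_geometry(BinaryMask(g))
        assert d.diameter_px == pytest.approx(30, abs=1)

    def test_matches_orientation_grid_brute_force_on_random_convex_shapes(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            mask = make_convex_blob(rng)
            impl = rm.disc_geometry(mask).diameter_px
            oracle = brute_force_min_rect_long_side(mask)
            assert impl == pytest.approx(oracle, abs=1.0)

    def test_mm_conversion_uses_mask_scale(self):
        g = np.zeros((30, 30), dtype=bool)
        g[10:20, 10:20] = True
        d = rm.disc_geometry(BinaryMask(g, scale_um_per_px=12.2))
        assert d.diameter_mm == pytest.approx(10 * 12.2 / 1000)

    def test_empty_mask_errors_and_single_pixel_warns(self):
        with pytest.raises(ValueError, match="empty"):
            rm.disc_geometry(BinaryMask(np.zeros((5, 5), dtype=bool)))
        g = np.zeros((5, 5), dtype=bool)
        g[2, 2] = True
        with pytest.warns(UserWarning, match="degenerate"):
            d = rm.disc_geometry(BinaryMask(g))
        assert d.diameter_px == 1.0


class TestAnnulus:
    def test_default_radii_are_dd_multiples(self):
        disc = rm.DiscGeometry((600.0, 700.0), 110.6, 1.35)
        ann = rm.make_annulus(disc)
        assert ann.inner_radius_px == pytest.approx(55.3)
        assert ann.outer_radius_px == pytest.approx(331.8)

    def test_zero_inner_gives_filled_circle(self):
        disc = rm.DiscGeometry((50.0, 50.0), 20.0, 0.244)
        ann = rm.make_annulus(disc, inner_dd=0.0, outer_dd=1.0)
        m = ann.pixel_mask((100, 100))
        assert m[50, 50]  # center included

    def test_pixel_mask_matches_per_pixel_brute_force(self):
        disc = rm.DiscGeometry((600.0, 700.0), 110.6, 1.35)
        ann = rm.make_annulus(disc)
        m = ann.pixel_mask((1200, 1600))
        count = 0
        rr, cc = np.meshgrid(np.arange(1200), np.arange(1600), indexing="ij")
        d = np.hypot(rr - 600.0, cc - 700.0)
        brute = (d >= ann.inner_radius_px) & (d <= ann.outer_radius_px)
        assert (m == brute).all()

    def test_inverted_bounds_rejected(self):
        disc = rm.DiscGeometry((50.0, 50.0), 20.0, 0.244)
        with pytest.raises(ValueError):
            rm.make_annulus(disc, inner_dd=3.0, outer_dd=0.5)


class TestSkeleton:
    def test_straight_tube_yields_single_path_of_tube_length(self):
        scene = rm.generate_tube_scene(7, 0, 100)
        sk = rm.skeletonize(scene.vessel_mask)
        assert len(sk.segments) == 1
        assert len(sk.branch_points) == 0
        # thinning erodes up to ~(w-1)/2 px per end
        assert 100 - 7 <= sk.n_pixels <= 100 + 2

    def test_y_union_topology(self, y_mask):
        sk = rm.skeletonize(y_mask)
        assert len(sk.branch_points) == 1
        assert len(sk.end_points) == 3
        assert len(sk.segments) == 3

    def test_every_skeleton_pixel_in_some_segment(self, y_mask):
        sk = rm.skeletonize(y_mask)
        covered = {tuple(p) for seg in sk.segments for p in seg}
        assert covered == {tuple(p) for p in sk.pixels}

    def test_skeleton_subset_of_mask(self, tree_scene):
        sk = rm.skeletonize(tree_scene.vessel_mask)
        assert tree_scene.vessel_mask.grid[sk.pixels[:, 0], sk.pixels[:, 1]].all()

    def test_endpoint_count_tracks_truth_terminals(self, tree_scene):
        clean = BinaryMask(tree_scene.vessel_mask.grid
                           & ~tree_scene.disc_mask.grid)
        sk = rm.skeletonize(clean)
        has_child = {s.parent for s in tree_scene.truth_segments}
        terminals = sum(1 for i, _ in enumerate(tree_scene.truth_segments)
                        if i not in has_child)
        assert len(sk.end_points) == pytest.approx(terminals, rel=0.10)

    def test_empty_mask_gives_empty_skeleton(self):
        sk = rm.skeletonize(BinaryMask(np.zeros((10, 10), dtype=bool)))
        assert sk.n_pixels == 0 and sk.segments == []


class TestFractalDimension:
    def test_line_square_sierpinski_oracles(self):
        line = np.zeros((1200, 1600), dtype=bool)
        line[600, 300:1300] = True
        assert rm.fractal_dimension(BinaryMask(line)) == pytest.approx(1.0, abs=0.05)
        square = np.ones((512, 512), dtype=bool)
        assert rm.fractal_dimension(BinaryMask(square)) == pytest.approx(2.0, abs=0.05)
        assert rm.fractal_dimension(sierpinski(7)) == pytest.approx(
            np.log(3) / np.log(2), abs=0.05)

    def test_too_few_pixels_errors_naming_threshold(self):
        g = np.zeros((600, 600), dtype=bool)
        g[10, 10:40] = True
        with pytest.raises(ValueError, match="100"):
            rm.fractal_dimension(BinaryMask(g))

    def test_region_restriction_filters_pixels(self):
        g = np.zeros((600, 600), dtype=bool)
        g[300, :] = True  # line through the whole frame
        roi = rm.AnnulusROI((300.0, 300.0), 0.0, 100.0)
        inside = rm.fractal_dimension(BinaryMask(g), region=roi)
        assert inside == pytest.approx(1.0, abs=0.1)


class TestCaliber:
    @pytest.mark.parametrize("width", [3, 5, 7, 9, 15])
    @pytest.mark.parametrize("orientation", [0, 30, 45, 90])
    def test_recovers_tube_width(self, width, orientation):
        scene = rm.generate_tube_scene(width, orientation, 200)
        sk = rm.skeletonize(scene.vessel_mask)
        roi = rm.AnnulusROI((200.0, 200.0), 0.0, 90.0)
        assert rm.mean_caliber(scene.vessel_mask, sk, roi) == pytest.approx(
            width, abs=0.5)

    def test_two_tube_mean_is_pixelwise_unweighted(self):
        g = np.zeros((200, 300), dtype=bool)
        from retmorph.synthetic import rasterize_tube
        rasterize_tube(g.shape, np.array([[60.0, 50.0], [60.0, 250.0]]), 2.5, out=g)
        rasterize_tube(g.shape, np.array([[140.0, 50.0], [140.0, 250.0]]), 4.5, out=g)
        mask = BinaryMask(g)
        sk = rm.skeletonize(mask)
        roi = rm.AnnulusROI((100.0, 150.0), 0.0, 140.0)
        assert rm.mean_caliber(mask, sk, roi) == pytest.approx(7.0, abs=0.5)

    def test_rotation_robustness(self):
        vals = []
        for ori in (0, 45):
            scene = rm.generate_tube_scene(9, ori, 200)
            sk = rm.skeletonize(scene.vessel_mask)
            roi = rm.AnnulusROI((200.0, 200.0), 0.0, 90.0)
            vals.append(rm.mean_caliber(scene.vessel_mask, sk, roi))
        assert abs(vals[0] - vals[1]) <= 0.5

    def test_empty_roi_errors(self):
        scene = rm.generate_tube_scene(7, 0, 200)
        sk = rm.skeletonize(scene.vessel_mask)
        far = rm.AnnulusROI((10.0, 10.0), 0.0, 5.0)
        with pytest.raises(ValueError, match="eligible"):
            rm.mean_caliber(scene.vessel_mask, sk, far)


class TestDensity:
    def test_empty_and_full_masks(self):
        roi = rm.AnnulusROI((50.0, 50.0), 10.0, 40.0)
        empty = BinaryMask(np.zeros((100, 100), dtype=bool))
        full = BinaryMask(np.ones((100, 100), dtype=bool))
        assert rm.vessel_density(empty, roi) == 0.0
        assert rm.vessel_density(full, roi) == 1.0

    def test_half_plane_symmetry(self):
        g = np.zeros((101, 101), dtype=bool)
        g[:50, :] = True  # upper half-plane, boundary row excluded
        roi = rm.AnnulusROI((50.0, 50.0), 10.0, 45.0)
        # only the all-background boundary row 50 breaks the symmetry
        assert rm.vessel_density(BinaryMask(g), roi) == pytest.approx(0.5, abs=0.01)

    def test_exact_against_brute_force_recount(self, tree_scene):
        disc = rm.disc_geometry(tree_scene.disc_mask)
        roi = rm.make_annulus(disc)
        d = rm.vessel_density(tree_scene.vessel_mask, roi)
        rr, cc = np.meshgrid(np.arange(1200), np.arange(1600), indexing="ij")
        dist = np.hypot(rr - disc.center[0], cc - disc.center[1])
        member = (dist >= roi.inner_radius_px) & (dist <= roi.outer_radius_px)
        brute = (tree_scene.vessel_mask.grid & member).sum() / member.sum()
        assert d == brute  # exact integer ratio

    def test_empty_roi_rejected(self):
        roi = rm.AnnulusROI((500.0, 500.0), 10.0, 40.0)  # fully off-frame
        with pytest.raises(ValueError):
            rm.vessel_density(BinaryMask(np.zeros((50, 50), dtype=bool)), roi)


class TestCurvature:
    def test_straight_tube_reads_zero(self):
        sk = rm.skeletonize(rm.generate_tube_scene(7, 0, 200).vessel_mask)
        assert rm.mean_curvature(sk) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("radius", [50, 100, 200, 400])
    def test_arc_recovers_reciprocal_radius(self, radius):
        sk = rm.skeletonize(rm.generate_arc_scene(radius, 7, 160).vessel_mask)
        assert rm.mean_curvature(sk) == pytest.approx(1.0 / radius, rel=0.10)

    def test_curvature_ratio_scaling(self):
        k50 = rm.mean_curvature(
            rm.skeletonize(rm.generate_arc_scene(50, 7, 160).vessel_mask))
        k200 = rm.mean_curvature(
            rm.skeletonize(rm.generate_arc_scene(200, 7, 160).vessel_mask))
        assert k50 / k200 == pytest.approx(4.0, rel=0.10)

    def test_too_short_segments_error(self):
        sk = rm.skeletonize(rm.generate_tube_scene(3, 0, 12).vessel_mask)
        with pytest.raises(ValueError, match="arclength"):
            rm.mean_curvature(sk, window_px=50)


class TestUnitConversion:
    @pytest.mark.parametrize("px, um", [(0, 0), (100, 1220), (110.66, 1350.052)])
    def test_px_to_um(self, px, um):
        assert rm.px_to_um(px) == pytest.approx(um)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            rm.px_to_um(1.0, scale_um_per_px=0.0)


class TestMeasureAll:
    def test_density_matches_generator_truth(self, tree_scene):
        m = rm.measure_all(tree_scene.vessel_mask, tree_scene.disc_mask)
        assert m.density == pytest.approx(tree_scene.truth_density, abs=0.01)

    def test_mirror_invariance(self):
        # frame sides are multiples of every box-counting scale, so even
        # the anchored box grid maps onto itself under reflection
        p = rm.VesselTreeParams(seed=3, image_height_px=1024, image_width_px=1536,
                                disc_center=(512.0, 700.0))
        scene = rm.generate_vessel_tree(p)
        m = rm.measure_all(scene.vessel_mask, scene.disc_mask)
        vm = BinaryMask(scene.vessel_mask.grid[:, ::-1].copy())
        dm = BinaryMask(scene.disc_mask.grid[:, ::-1].copy())
        mm = rm.measure_all(vm, dm)
        for k, v in m.as_dict().items():
            assert mm.as_dict()[k] == pytest.approx(v, rel=0.01), k

    def test_translation_invariance(self, small_tree_params):
        # embed the same compact scene at two offsets differing by a
        # dyadic shift (256 px), which every box-counting scale divides
        scene = rm.generate_vessel_tree(small_tree_params)
        h, w = scene.vessel_mask.shape
        metrics = []
        for dc in (0, 256):
            vg = np.zeros((1200, 1600), dtype=bool)
            dg = np.zeros((1200, 1600), dtype=bool)
            vg[100:100 + h, dc:dc + w] = scene.vessel_mask.grid
            dg[100:100 + h, dc:dc + w] = scene.disc_mask.grid
            metrics.append(rm.measure_all(BinaryMask(vg), BinaryMask(dg)))
        a, b = (m.as_dict() for m in metrics)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9), k

    def test_scale_change_moves_physical_units_only(self, small_tree_params):
        scene = rm.generate_vessel_tree(small_tree_params)
        m1 = rm.measure_all(scene.vessel_mask, scene.disc_mask)
        m2 = rm.measure_all(scene.vessel_mask.with_scale(24.4),
                            scene.disc_mask.with_scale(24.4))
        assert m2.caliber_um == pytest.approx(2 * m1.caliber_um)
        assert m2.disc_diameter_mm == pytest.approx(2 * m1.disc_diameter_mm)
        assert m2.fractal_dimension == m1.fractal_dimension
        assert m2.density == m1.density
        assert m2.curvature_px_inv == m1.curvature_px_inv

    def test_shape_mismatch_rejected(self):
        a = BinaryMask(np.zeros((10, 10), dtype=bool))
        b = BinaryMask(np.zeros((20, 20), dtype=bool))
        with pytest.raises(ValueError, match="shape"):
            rm.measure_all(a, b)

    def test_stage_labels_in_errors(self):
        a = BinaryMask(np.zeros((64, 64), dtype=bool))
        with pytest.raises(ValueError, match=r"\[disc_geometry\]"):
            rm.measure_all(a, a)
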