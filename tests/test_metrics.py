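"""Geometric statistics: length, tortuosity, twist, helicity, area, density."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import ConvexHull

from spindlegraph import metrics
from spindlegraph.graph_model import (
    Microtubule,
    Spindle,
    build_kfibers,
    infer_plus_minus_ends,
    pair_sister_kfibers,
    preprocess,
    transform_rigid,
)
from spindlegraph.synthetic import SpindleRecipe, generate_spindle, make_half_circle

from conftest import straight_kmt


class TestLength:
    def test_right_angle_micron_path(self):
        pts = 1000.0 * np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]])
        assert metrics.polyline_length(pts) == pytest.approx(2000.0)

    def test_345_segment(self):
        assert metrics.polyline_length(np.array([[0.0, 0, 0], [3, 4, 0]])) == pytest.approx(5.0)

    def test_dense_half_circle(self):
        mt = make_half_circle(1000.0, 2001)
        assert metrics.polyline_length(mt) == pytest.approx(math.pi * 1000, rel=1e-3)

    def test_length_distribution_summary(self):
        mts = [
            straight_kmt(i, (0, 0, 0), (0, 0, 1000.0 * (i + 1)), fiber_id=1)
            for i in range(3)
        ]
        sp = Spindle(1, mts)
        table, summary = metrics.length_distribution(sp)
        assert len(table.frame) == 3
        assert table.summary["mean_nm"] == pytest.approx(2000.0)
        assert table.summary["n"] == 3

    def test_empty_class_warns(self):
        sp = Spindle(1, [Microtubule(0, np.array([[0.0, 0, 0], [1, 0, 0]]))])
        with pytest.warns(UserWarning):
            table, _ = metrics.length_distribution(sp)
        assert table.frame.empty

    def test_generator_mean_length_recovered(self):
        """Sample mean of measured KMT lengths within 3 SE of the recipe mean."""
        recipe = SpindleRecipe(seed=21, n_fiber_pairs=4, kmts_per_fiber=5,
                               fiber_length_um=(3.0, 0.5), n_nonkmt=0)
        graph, truth = generate_spindle(recipe)
        sp = preprocess(Spindle.from_spatial_graph(graph, graph_id=1))
        lengths = np.array([metrics.polyline_length(m) for m in sp.kmts()])
        se = 500.0 / math.sqrt(len(lengths))
        assert abs(lengths.mean() - 3000.0) <= 3 * se


class TestTortuosity:
    def test_straight_line_is_one(self):
        pts = np.column_stack([np.arange(0, 2001, 20.0), np.zeros(101), np.zeros(101)])
        assert metrics.tortuosity(pts) == pytest.approx(1.0, abs=1e-12)

    def test_half_circle_is_157(self):
        assert round(metrics.tortuosity(make_half_circle(1000.0, 1001)), 2) == 1.57

    def test_closed_curve_reports_infinity(self):
        theta = np.linspace(0, 2 * math.pi, 100)
        circle = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        circle[-1] = circle[0]
        assert math.isinf(metrics.tortuosity(circle))

    def test_matches_direct_ratio_on_random_walks(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = np.cumsum(rng.normal(0, 30, (int(rng.integers(3, 50)), 3)), axis=0)
            # independent re-computation by direct summation
            L = sum(
                math.dist(tuple(pts[i]), tuple(pts[i + 1])) for i in range(len(pts) - 1)
            )
            l = math.dist(tuple(pts[0]), tuple(pts[-1]))
            assert metrics.tortuosity(pts) == pytest.approx(L / l, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_never_below_one(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-100, 100, (int(rng.integers(2, 20)), 3))
        tau = metrics.tortuosity(pts)
        assert tau >= 1.0 - 1e-12

    def test_local_windows_cover_curved_region(self):
        mt = make_half_circle(1000.0, 721)
        centers, values = metrics.local_tortuosity(mt, window=500.0)
        assert len(centers) == int(math.pi * 1000 // 500)
        # a 500 nm window on a 1000 nm-radius circle subtends 0.5 rad
        expected = 0.25 / math.sin(0.25)
        np.testing.assert_allclose(values, expected, rtol=1e-3)


def _helix_bundle_spindle(seed=31, pitch_um=10.0):
    recipe = SpindleRecipe(
        seed=seed, n_fiber_pairs=2, kmts_per_fiber=4, helix_pitch_um=pitch_um,
        plate_radius_nm=200.0, bundle_radius_nm=100.0, noise_sigma_nm=0.0,
        n_nonkmt=0, fiber_length_um=(4.0, 0.0),
    )
    graph, truth = generate_spindle(recipe)
    return preprocess(Spindle.from_spatial_graph(graph, graph_id=1)), truth


class TestTwist:
    def test_straight_bundle_has_zero_twist(self, small_spindle):
        spindle, _ = small_spindle
        for fib in spindle.fibers.values():
            _, means, _ = metrics.local_twist(fib, spindle.axis_unit)
            np.testing.assert_allclose(np.nan_to_num(means), 0, atol=1e-6)

    def test_helix_bundle_matches_closed_form(self):
        # pitch 10 um, 500 nm steps -> 18 deg per step
        sp, truth = _helix_bundle_spindle()
        for fid, fib in sp.fibers.items():
            _, means, _ = metrics.local_twist(fib, sp.axis_unit)
            expected = truth.expected_local_twist_deg
            sign = 1.0 if fib.pole_id == 2 else -1.0
            assert np.nanmean(means) == pytest.approx(sign * expected, rel=0.05)

    def test_total_twist_is_sum_of_local(self):
        sp, _ = _helix_bundle_spindle()
        for fib in sp.fibers.values():
            _, means, _ = metrics.local_twist(fib, sp.axis_unit)
            assert metrics.total_twist(fib, sp.axis_unit) == pytest.approx(
                np.nansum(means), rel=1e-9
            )

    def test_mirror_reflection_negates_twist(self):
        sp, _ = _helix_bundle_spindle()
        mirror = np.diag([-1.0, 1.0, 1.0])
        flipped = transform_rigid(sp, mirror, np.zeros(3))
        for fid in sp.fibers:
            t0 = metrics.total_twist(sp.fibers[fid], sp.axis_unit)
            t1 = metrics.total_twist(flipped.fibers[fid], flipped.axis_unit)
            assert t1 == pytest.approx(-t0, rel=1e-6, abs=1e-9)


class TestHelicity:
    def test_straight_on_axis_fiber_is_zero(self):
        mt = straight_kmt(0, (0, 0, 4000), (0, 0, 1000), fiber_id=1)
        sp = Spindle(1, [mt], pole1=np.zeros(3), pole2=np.array([0.0, 0, 10000.0]))
        sp = build_kfibers(infer_plus_minus_ends(sp))
        assert metrics.helicity(sp.fibers[1], sp.pole1, sp.axis_unit) == 0.0

    def test_helix_center_curve_matches_360_over_pitch(self):
        sp, truth = _helix_bundle_spindle()
        for fid, fib in sp.fibers.items():
            expected = truth.expected_helicity_deg_per_um[str(fid)]
            h = metrics.helicity(fib, sp.pole1, sp.axis_unit)
            assert h == pytest.approx(expected, rel=0.05)

    def test_sign_flips_under_mirror(self):
        sp, _ = _helix_bundle_spindle()
        mirror = np.diag([-1.0, 1.0, 1.0])
        flipped = transform_rigid(sp, mirror, np.zeros(3))
        for fid in sp.fibers:
            h0 = metrics.helicity(sp.fibers[fid], sp.pole1, sp.axis_unit)
            h1 = metrics.helicity(flipped.fibers[fid], flipped.pole1, flipped.axis_unit)
            assert h1 == pytest.approx(-h0, rel=1e-6)

    def test_single_point_center_curve_is_nan(self):
        fib = dataclasses.replace(
            _helix_bundle_spindle()[0].fibers[1],
            center_curve=np.zeros((1, 3)),
        )
        assert math.isnan(metrics.helicity(fib, np.zeros(3), np.array([0, 0, 1.0])))


class TestArea:
    def test_square_of_four_kmts(self):
        pts = np.array([[0.0, 0], [100, 0], [100, 100], [0, 100]])
        assert metrics.alpha_shape_area(pts) == pytest.approx(10_000.0)

    def test_equilateral_triangle(self):
        pts = np.array([[0.0, 0], [100, 0], [50, 50 * math.sqrt(3)]])
        assert metrics.alpha_shape_area(pts) == pytest.approx(
            math.sqrt(3) / 4 * 100**2
        )

    def test_infinite_alpha_equals_independent_convex_hull(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            pts = rng.uniform(0, 300, (int(rng.integers(4, 40)), 2))
            assert metrics.alpha_shape_area(pts) == pytest.approx(
                ConvexHull(pts).volume, rel=1e-9
            )

    def test_area_monotone_in_alpha_radius(self):
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 300, (30, 2))
        radii = [20.0, 50.0, 100.0, 300.0, math.inf]
        areas = [metrics.alpha_shape_area(pts, r) for r in radii]
        assert all(a <= b + 1e-9 for a, b in zip(areas, areas[1:]))

    def test_degenerate_inputs_are_nan(self):
        assert math.isnan(metrics.alpha_shape_area(np.array([[0.0, 0], [1, 1]])))
        collinear = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert math.isnan(metrics.alpha_shape_area(collinear))

    def test_fiber_cross_section_square_bundle(self):
        offsets = [(0, 0), (100, 0), (100, 100), (0, 100)]
        mts = [
            straight_kmt(i, (ox, oy, 4000), (ox, oy, 1000), n=100, fiber_id=1)
            for i, (ox, oy) in enumerate(offsets)
        ]
        sp = Spindle(1, mts, pole1=np.zeros(3), pole2=np.array([0.0, 0, 10000.0]))
        sp = build_kfibers(infer_plus_minus_ends(sp))
        pos, areas, counts = metrics.fiber_cross_section_area(sp.fibers[1], sp)
        assert np.all(counts == 4)
        np.testing.assert_allclose(areas, 10_000.0, rtol=1e-9)
        dens = metrics.kmt_density(areas, counts)
        np.testing.assert_allclose(dens, 400.0, rtol=1e-9)  # 4 per 10^4 nm^2

    def test_density_recovered_from_fixed_packing(self):
        recipe = SpindleRecipe(seed=23, n_fiber_pairs=2, kmts_per_fiber=5,
                               noise_sigma_nm=0.0, n_nonkmt=0,
                               fiber_length_um=(3.0, 0.0))
        graph, truth = generate_spindle(recipe)
        sp = preprocess(Spindle.from_spatial_graph(graph, graph_id=1))
        for fib in sp.fibers.values():
            _, areas, counts = metrics.fiber_cross_section_area(fib, sp)
            dens = np.nanmean(metrics.kmt_density(areas, counts))
            assert dens == pytest.approx(truth.expected_density_per_um2, rel=0.10)


class TestKinetochoreStats:
    def _two_fibers(self, n1=5, n2=7):
        # member x-offsets centered on 0 so both centroids sit on the axis
        mts = []
        mid = 0
        for i in range(n1):
            x = (i - (n1 - 1) / 2) * 50
            mts.append(straight_kmt(mid, (x, 0, 4500), (x, 0, 1000), fiber_id=1))
            mid += 1
        for i in range(n2):
            x = (i - (n2 - 1) / 2) * 50
            mts.append(straight_kmt(mid, (x, 0, 5500), (x, 0, 9000), fiber_id=2))
            mid += 1
        sp = Spindle(1, mts, pole1=np.zeros(3), pole2=np.array([0.0, 0, 10000.0]))
        return pair_sister_kfibers(build_kfibers(infer_plus_minus_ends(sp)))

    def test_outer_kinetochore_distance_between_centroids(self):
        sp = self._two_fibers()
        table = metrics.outer_kinetochore_distance(sp)
        assert len(table.frame) == 1
        assert table.frame["distance_nm"].iloc[0] == pytest.approx(1000.0)

    def test_single_kmt_fiber_centroid_is_its_plus_end(self):
        sp = self._two_fibers(n1=1, n2=1)
        np.testing.assert_allclose(sp.fibers[1].plus_end_centroid, [0, 0, 4500])

    def test_sister_count_columns_are_crossed(self):
        sp = self._two_fibers()
        table, _ = metrics.kmt_number_stats(sp)
        frame = table.frame.set_index("fiber_id")
        assert frame.loc[1, "kmt_count"] == 5 and frame.loc[1, "sister_kmt_count"] == 7
        assert frame.loc[2, "kmt_count"] == 7 and frame.loc[2, "sister_kmt_count"] == 5

    def test_zero_variance_counts_flagged(self):
        sp = self._two_fibers(n1=4, n2=4)
        _, corr = metrics.kmt_number_stats(sp)
        assert (corr.frame["flag"] != "").all()
        assert corr.frame["pearson_r"].isna().all()

    def test_axial_count_gradient_sign_recovered(self):
        """Counts generated increasing along the axis give positive Pearson r
        in >=95% of 50 seeds."""
        hits = 0
        for seed in range(50):
            recipe = SpindleRecipe(
                seed=seed, n_fiber_pairs=5, kmts_per_fiber=6, n_nonkmt=0,
                plate_z_jitter_nm=1000.0, kmt_count_slope_per_um=3.0,
                kmt_count_noise=1.0, fiber_length_um=(3.0, 0.3),
            )
            graph, _ = generate_spindle(recipe)
            sp = preprocess(Spindle.from_spatial_graph(graph, graph_id=1))
            _, corr = metrics.kmt_number_stats(sp)
            r = corr.frame.set_index("covariate").loc["axial_position_nm", "pearson_r"]
            if r > 0:
                hits += 1
        assert hits / 50 >= 0.95


class TestRigidInvariance:
    def _random_rigid(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        ang = rng.uniform(0, 2 * math.pi)
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)
        return R, rng.uniform(-3000, 3000, 3)

    def test_all_metrics_invariant_under_rigid_motion(self, small_spindle):
        spindle, _ = small_spindle
        R, t = self._random_rigid(99)
        moved = transform_rigid(spindle, R, t)
        for fid in spindle.fibers:
            f0, f1 = spindle.fibers[fid], moved.fibers[fid]
            assert metrics.total_twist(f1, moved.axis_unit) == pytest.approx(
                metrics.total_twist(f0, spindle.axis_unit), rel=1e-6, abs=1e-6
            )
            h0 = metrics.helicity(f0, spindle.pole1, spindle.axis_unit)
            h1 = metrics.helicity(f1, moved.pole1, moved.axis_unit)
            assert h1 == pytest.approx(h0, rel=1e-6, abs=1e-6)
            _, a0, c0 = metrics.fiber_cross_section_area(f0, spindle)
            _, a1, c1 = metrics.fiber_cross_section_area(f1, moved)
            np.testing.assert_array_equal(c0, c1)
            np.testing.assert_allclose(a1, a0, rtol=1e-6)
        for m0, m1 in zip(spindle.microtubules, moved.microtubules):
            assert metrics.polyline_length(m1) == pytest.approx(
                metrics.polyline_length(m0), rel=1e-6
            )
            assert metrics.tortuosity(m1) == pytest.approx(
                metrics.tortuosity(m0), rel=1e-6
            )
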