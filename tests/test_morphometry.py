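"""The nine quantitative parameters: calibers, tortuosity, angles, density,
fractal dimension, AVR, and disc/cup metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from retinavasc.geometry import Ellipse, circle
from retinavasc.graph import Node, Segment, VesselGraph, build_graph, skeletonize
from retinavasc.morphometry import (
    InsufficientScalesError,
    MorphometryConfig,
    arteriole_venule_ratio,
    disc_cup_metrics,
    fractal_dimension,
    measure_branch_angle,
    measure_caliber,
    measure_tortuosity,
    vessel_density,
)
from retinavasc.simulate import _stamp_polyline


def straight_segment(radius=4.0, n=120, label="artery"):
    pts = np.column_stack([np.arange(n, dtype=float), np.full(n, 50.0)])
    return Segment(0, pts, np.full(n, radius), label, (0, 1))


class TestCaliber:
    def test_constant_radius_band(self):
        s = straight_segment(radius=4.0)
        # stamped truth is 2r = 8 px; estimator reads the EDT radius directly
        assert measure_caliber(s, pitch=10.0) == pytest.approx(80.0, abs=10.0)

    def test_measured_taper_from_rasterized_band(self):
        # band tapering from 10 px to 6 px width: graph-measured mean within
        # 0.5 px of the 8 px mid-caliber
        # tilted so raster quantization dithers out along the centerline
        m = np.zeros((110, 220), dtype=bool)
        pts = np.column_stack([np.linspace(10, 210, 201), np.linspace(25.0, 85.0, 201)])
        _stamp_polyline(m, pts, np.linspace(5.0, 3.0, 201))
        skel = skeletonize(m, 5)
        g = build_graph(skel, m)
        seg = max(g.segments, key=lambda s: s.arc_length)
        c = measure_caliber(seg, pitch=1.0)
        assert c == pytest.approx(8.0, abs=0.5)

    def test_pitch_scales_to_micrometers(self):
        s = straight_segment(radius=4.0)
        assert measure_caliber(s, pitch=20.0) == pytest.approx(
            2.0 * measure_caliber(s, pitch=10.0), rel=1e-12
        )

    def test_too_few_points_undefined(self):
        s = straight_segment(n=4)
        assert measure_caliber(s, pitch=10.0) is None


class TestTortuosity:
    def test_straight_is_exactly_zero(self):
        pts = np.column_stack([np.arange(200.0), 0.37 * np.arange(200.0)])
        assert measure_tortuosity(pts) == 0.0

    def test_semicircle_matches_analytic(self):
        th = np.linspace(0.0, np.pi, 315)
        pts = np.column_stack([100.0 * np.cos(th), 100.0 * np.sin(th)])
        assert measure_tortuosity(pts) == pytest.approx(np.pi / 2.0 - 1.0, abs=1e-3)

    def test_sinusoid_matches_quadrature(self):
        a, lam, L = 5.0, 100.0, 199.0
        x = np.arange(0.0, 200.0)
        pts = np.column_stack([x, a * np.sin(2.0 * np.pi * x / lam)])
        arc = quad(
            lambda t: math.sqrt(1.0 + (a * 2.0 * np.pi / lam * math.cos(2.0 * np.pi * t / lam)) ** 2),
            0.0,
            L,
        )[0]
        chord = math.hypot(L, a * math.sin(2.0 * np.pi * L / lam))
        oracle = arc / chord - 1.0
        assert measure_tortuosity(pts) == pytest.approx(oracle, rel=0.01)

    def test_closed_loop_raises(self):
        th = np.linspace(0.0, 2.0 * np.pi, 200)
        pts = np.column_stack([50.0 * np.cos(th), 50.0 * np.sin(th)])
        with pytest.raises(ValueError, match="chord"):
            measure_tortuosity(pts)

    def test_short_run_undefined(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        assert measure_tortuosity(pts) is None

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_nonnegative_on_random_walk_paths(self, seed):
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, 1.0, size=(40, 2)) + np.array([2.0, 0.0])
        pts = np.cumsum(steps, axis=0)
        try:
            t = measure_tortuosity(pts)
        except ValueError:
            return
        if t is not None:
            assert t >= -1e-9


class TestBranchAngle:
    @staticmethod
    def y_graph(angle_deg=60.0, parent_r=5.0, child_r=3.5):
        """Rasterized symmetric Y with daughters at +/- angle/2 off the x axis."""
        m = np.zeros((300, 300), dtype=bool)
        node = np.array([150.0, 150.0])
        pts = np.column_stack([np.linspace(30, 150, 121), np.full(121, 150.0)])
        _stamp_polyline(m, pts, np.full(121, parent_r))
        half = math.radians(angle_deg / 2.0)
        for sign in (-1, 1):
            d = np.array([math.cos(sign * half), math.sin(sign * half)])
            p = node[None, :] + np.linspace(0, 120, 121)[:, None] * d[None, :]
            _stamp_polyline(m, p, np.full(121, child_r))
        skel = skeletonize(m, 5)
        return build_graph(skel, m)

    def test_symmetric_y_sixty_degrees(self):
        g = self.y_graph(60.0)
        bifs = [n for n in g.bifurcations() if n.degree == 3]
        assert len(bifs) == 1
        a = measure_branch_angle(g, bifs[0].id)
        assert a == pytest.approx(60.0, abs=2.0)

    def test_collinear_daughters_approach_180(self):
        g = self.y_graph(176.0, parent_r=4.0, child_r=2.8)
        bifs = [n for n in g.bifurcations() if n.degree == 3]
        assert len(bifs) == 1
        a = measure_branch_angle(g, bifs[0].id)
        assert a == pytest.approx(176.0, abs=4.0)

    def test_degree4_crossing_excluded(self):
        m = np.zeros((200, 200), dtype=bool)
        for p0, p1 in [((20.0, 100.0), (180.0, 100.0)), ((100.0, 20.0), (100.0, 180.0))]:
            pts = np.linspace(p0, p1, 161)
            _stamp_polyline(m, pts, np.full(161, 3.0))
        skel = skeletonize(m, 5)
        g = build_graph(skel, m)
        for n in g.bifurcations():
            if n.degree >= 4:
                assert measure_branch_angle(g, n.id) is None

    def test_out_of_range_bifurcation_excluded(self):
        g = self.y_graph(60.0)
        node = [n for n in g.bifurcations() if n.degree == 3][0]
        far_center = (0.0, 0.0)
        pd_px = 20.0  # 2 PD = 40 px, node is ~212 px away
        assert measure_branch_angle(g, node.id, far_center, pd_px) is None


class TestDensity:
    def test_trivial_full_and_fractional(self):
        m = np.ones((50, 50), dtype=bool)
        assert vessel_density(m) == 1.0
        m2 = np.zeros((100, 100), dtype=bool)
        m2[20:30, :] = True
        assert vessel_density(m2) == pytest.approx(0.10, abs=1e-12)

    def test_empty_region_raises(self):
        m = np.zeros((10, 10), dtype=bool)
        with pytest.raises(ValueError, match="empty region"):
            vessel_density(m, np.zeros((10, 10), dtype=bool))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce_count(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((40, 40)) < 0.3
        region = rng.random((40, 40)) < 0.7
        if not region.any():
            return
        count = sum(
            1 for y in range(40) for x in range(40) if m[y, x] and region[y, x]
        )
        total = int(region.sum())
        assert vessel_density(m, region) == count / total


class TestFractalDimension:
    def test_line_square_sierpinski(self):
        line = np.zeros((512, 512), dtype=bool)
        line[256, :] = True
        assert fractal_dimension(line) == pytest.approx(1.0, abs=0.05)
        square = np.ones((512, 512), dtype=bool)
        assert fractal_dimension(square) == pytest.approx(2.0, abs=0.05)
        yy, xx = np.mgrid[0:512, 0:512]
        sierpinski = (yy & xx) == 0  # depth-9 Sierpinski triangle
        assert fractal_dimension(sierpinski) == pytest.approx(math.log(3) / math.log(2), abs=0.05)

    def test_insufficient_scales_raises(self):
        tiny = np.ones((8, 8), dtype=bool)
        with pytest.raises(InsufficientScalesError):
            fractal_dimension(tiny)
        sparse = np.zeros((512, 512), dtype=bool)
        sparse[5, 5] = True
        with pytest.raises(InsufficientScalesError):
            fractal_dimension(sparse)


class TestAvrAndDiscCup:
    @staticmethod
    def two_class_graph(artery_w, vein_w, n=100):
        g = VesselGraph()
        g.nodes = [Node(i, (0.0, float(i)), 1, "endpoint") for i in range(8)]
        sid = 0
        for widths, label in ((artery_w, "artery"), (vein_w, "vein")):
            for w in widths:
                pts = np.column_stack([np.arange(n, dtype=float), np.full(n, 10.0 * sid)])
                g.segments.append(
                    Segment(sid, pts, np.full(n, w / 2.0), label, (2 * sid % 8, (2 * sid + 1) % 8))
                )
                sid += 1
        return g

    def test_avr_direct_arithmetic(self):
        g = self.two_class_graph([4.0, 4.0], [5.0, 5.0])
        assert arteriole_venule_ratio(g, pitch=10.0) == pytest.approx(0.8, rel=1e-9)

    def test_avr_equal_calibers_unity(self):
        g = self.two_class_graph([4.0], [4.0])
        assert arteriole_venule_ratio(g, pitch=10.0) == pytest.approx(1.0, rel=1e-9)

    def test_avr_missing_class_undefined(self):
        g = self.two_class_graph([4.0], [])
        assert arteriole_venule_ratio(g, pitch=10.0) is None

    def test_disc_cup_metrics_analytic(self):
        disc = circle((0.0, 0.0), 100.0)
        cup = circle((0.0, 0.0), 50.0)
        d, c, cdr = disc_cup_metrics(disc, cup, pitch=10.0)
        assert d == pytest.approx(math.pi, rel=1e-9)  # pi * (1 mm)^2
        assert cdr == pytest.approx(0.25, rel=1e-9)

    def test_containment_violation_raises(self):
        disc = circle((0.0, 0.0), 50.0)
        cup = circle((40.0, 0.0), 30.0)
        with pytest.raises(ValueError, match="containment"):
            disc_cup_metrics(disc, cup, pitch=10.0)


class TestInvariances:
    def test_mask_metrics_rotation_invariant(self, scene0):
        _, truth = scene0
        m = truth.vessel_mask
        r = np.rot90(m)
        assert vessel_density(m) == pytest.approx(vessel_density(r), rel=1e-12)
        assert fractal_dimension(m) == pytest.approx(fractal_dimension(r), abs=0.03)

    def test_caliber_scale_covariance(self):
        # same physical vessel at half the pixel pitch: px caliber doubles,
        # micrometer caliber is unchanged within tolerance
        calibers = []
        for pitch, radius in ((10.0, 4.0), (5.0, 8.0)):
            m = np.zeros((160, 300), dtype=bool)
            pts = np.column_stack([np.linspace(10, 290, 281), np.linspace(40.0, 120.0, 281)])
            _stamp_polyline(m, pts, np.full(281, radius))
            g = build_graph(skeletonize(m, 5), m)
            seg = max(g.segments, key=lambda s: s.arc_length)
            calibers.append(measure_caliber(seg, pitch=pitch))
        assert calibers[0] == pytest.approx(calibers[1], rel=0.05)
        assert calibers[0] == pytest.approx(80.0, rel=0.10)
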