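"""Polar reconstruction, GVF, snake evolution and plaque measurement."""

import numpy as np
import pytest
from skimage.draw import circle_perimeter

from carotidseg import ParameterError, PhantomSpec, make_artery_phantom
from carotidseg.segment import (ContourPolygon, circle_polygon, gvf,
                                plaque_area, polygon_area, reconstruct_side,
                                segment_artery, snake_evolve, to_polar_min)


def _circle_edges(shape, centre, radius):
    edges = np.zeros(shape, dtype=np.uint8)
    rr, cc = circle_perimeter(*centre, radius)
    edges[rr, cc] = 255
    return edges


class TestPolarMap:
    def test_rasterized_circle_covers_every_bin_near_radius(self):
        edges = _circle_edges((100, 100), (50, 50), 20)
        polar = to_polar_min(edges, (50, 50))
        assert polar.present.all()
        assert np.all((polar.distances >= 19) & (polar.distances <= 21))

    def test_empty_edge_image_all_bins_absent(self):
        polar = to_polar_min(np.zeros((50, 50), dtype=np.uint8), (25, 25))
        assert not polar.present.any()

    def test_single_pixel_covers_its_angular_footprint_only(self):
        edges = np.zeros((64, 64), dtype=np.uint8)
        edges[32, 47] = 255  # at angle 0, distance 15
        polar = to_polar_min(edges, (32, 32))
        present = np.flatnonzero(polar.present)
        # a unit square at distance 15 subtends about +-1.9 degrees
        assert 0 in present
        assert set(present) <= {0, 1, 358, 359}
        assert polar.distances[0] == pytest.approx(15.0)

    def test_centre_outside_rejected(self):
        with pytest.raises(ParameterError):
            to_polar_min(np.zeros((10, 10)), (20, 5))


class TestReconstruction:
    def test_complete_circle_untouched(self):
        edges = _circle_edges((100, 100), (50, 50), 20)
        polar = to_polar_min(edges, (50, 50))
        res = reconstruct_side(edges, polar, 20)
        assert res.added.size == 0
        assert np.array_equal(res.edges, edges)

    def test_deleted_arc_refilled_at_radius(self):
        r = 30
        edges = _circle_edges((120, 120), (60, 60), r)
        ys, xs = np.nonzero(edges)
        ang = np.degrees(np.arctan2(ys - 60.0, xs - 60.0)) % 360
        kill = (ang >= 150) & (ang < 210)
        edges[ys[kill], xs[kill]] = 0
        polar = to_polar_min(edges, (60, 60))
        res = reconstruct_side(edges, polar, r)
        assert res.added.shape[0] > 0
        d = np.hypot(res.added[:, 0] - 60.0, res.added[:, 1] - 60.0)
        assert np.all(np.abs(d - r) <= 0.5)
        # every bin of the output is covered within t = r + 4
        polar2 = to_polar_min(res.edges, (60, 60))
        assert polar2.present.all()
        assert np.nanmax(polar2.distances) <= r + 4

    def test_far_spurious_edge_triggers_fill_and_is_retained(self):
        r = 20
        edges = np.zeros((100, 100), dtype=np.uint8)
        edges[50, 50 + r + 10] = 255  # only evidence at distance r + 10 > r + 4
        polar = to_polar_min(edges, (50, 50))
        res = reconstruct_side(edges, polar, r)
        assert res.edges[50, 50 + r + 10] == 255          # original preserved
        d = np.hypot(res.added[:, 0] - 50.0, res.added[:, 1] - 50.0)
        assert np.all(np.abs(d - r) <= 0.5)

    def test_output_superset_of_input(self):
        edges = _circle_edges((100, 100), (50, 50), 22)
        edges[:, 50:] = 0  # half deleted
        polar = to_polar_min(edges, (50, 50))
        res = reconstruct_side(edges, polar, 22)
        assert np.all(res.edges[edges > 0] == 255)


class TestGvf:
    def test_uniform_map_gives_zero_field(self):
        f = gvf(np.full((40, 40), 7.0), iterations=10)
        assert np.allclose(f.u, 0) and np.allclose(f.v, 0)

    def test_field_points_towards_step_edge(self):
        edge = np.zeros((40, 40))
        edge[:, 20] = 1.0
        f = gvf(edge, iterations=60)
        assert f.u[20, 14] > 0   # left of the edge: force to the right
        assert f.u[20, 26] < 0   # right of the edge: force to the left

    def test_zero_iterations_returns_raw_gradient(self):
        rng = np.random.default_rng(0)
        edge = rng.random((20, 20))
        f = gvf(edge, iterations=0)
        fy, fx = np.gradient(edge / edge.max())
        assert np.allclose(f.u, fx) and np.allclose(f.v, fy)

    def test_unstable_step_rejected(self):
        with pytest.raises(ParameterError):
            gvf(np.zeros((10, 10)), mu=0.3, dt=1.0)  # 4*mu*dt = 1.2

    def test_larger_mu_flattens_field(self):
        edge = np.zeros((40, 40))
        edge[:, 20] = 1.0
        weak = gvf(edge, mu=0.05, iterations=40)
        strong = gvf(edge, mu=0.25, iterations=40)
        assert np.hypot(strong.u, strong.v).max() <= np.hypot(weak.u, weak.v).max()


class TestSnake:
    def test_tension_shrinks_contour_in_zero_field(self):
        field = gvf(np.zeros((101, 101)), iterations=1)
        init = circle_polygon((50, 50), 35)
        out = snake_evolve(init, field, iterations=100, convergence_tol=1e-6)
        r = np.hypot(out.vertices[:, 0] - 50, out.vertices[:, 1] - 50)
        assert r.mean() < 35

    def test_converges_to_circle_edge(self):
        edges = _circle_edges((101, 101), (50, 50), 30)
        field = gvf(edges)
        out = snake_evolve(circle_polygon((50, 50), 40), field)
        r = np.hypot(out.vertices[:, 0] - 50, out.vertices[:, 1] - 50)
        assert abs(r.mean() - 30) <= 1.5

    def test_enters_plaque_concavity(self, plaque_phantom):
        spec, frame, _ = plaque_phantom
        res = segment_artery(frame, (64, 64, spec.radius), spec.mm_per_px)
        r = np.hypot(res.contour.vertices[:, 0] - 64, res.contour.vertices[:, 1] - 64)
        assert r.min() <= spec.radius - 10.0 + 2.0

    def test_bitwise_deterministic(self):
        edges = _circle_edges((101, 101), (50, 50), 30)
        field = gvf(edges)
        a = snake_evolve(circle_polygon((50, 50), 40), field)
        b = snake_evolve(circle_polygon((50, 50), 40), field)
        assert np.array_equal(a.vertices, b.vertices)

    def test_too_few_vertices_rejected(self):
        field = gvf(np.zeros((20, 20)), iterations=1)
        tiny = ContourPolygon(vertices=np.array([[1.0, 1], [2, 2], [3, 1]]))
        with pytest.raises(ParameterError):
            snake_evolve(tiny, field)


class TestAreas:
    def test_unit_square(self):
        sq = ContourPolygon(vertices=np.array([[0., 0], [0, 1], [1, 1], [1, 0]]))
        assert polygon_area(sq, 1.0) == pytest.approx(1.0)

    def test_ten_px_square_at_point_one_mm(self):
        sq = ContourPolygon(vertices=np.array([[0., 0], [0, 10], [10, 10], [10, 0]]))
        assert polygon_area(sq, 0.1) == pytest.approx(1.0)

    def test_orientation_invariant(self):
        sq = ContourPolygon(vertices=np.array([[0., 0], [0, 10], [10, 10], [10, 0]]))
        rev = ContourPolygon(vertices=sq.vertices[::-1])
        assert polygon_area(sq, 1.0) == polygon_area(rev, 1.0)

    def test_degenerate_polygon_rejected(self):
        line = ContourPolygon(vertices=np.array([[0., 0], [1, 1], [0, 0], [1, 1]]))
        with pytest.raises(ParameterError):
            polygon_area(line, 1.0)

    def test_identical_polygons_give_zero_plaque(self):
        c = circle_polygon((50, 50), 30)
        m = plaque_area(c, c, 0.1)
        assert m.plaque_area_mm2 == 0.0 and not m.clamped

    def test_annulus_area_difference(self):
        m = plaque_area(circle_polygon((0, 0), 40), circle_polygon((0, 0), 30), 0.1)
        assert m.plaque_area_mm2 == pytest.approx(np.pi * (40**2 - 30**2) * 0.01,
                                                  abs=0.05)

    def test_negative_difference_clamps_with_flag(self):
        m = plaque_area(circle_polygon((0, 0), 30), circle_polygon((0, 0), 40), 0.1)
        assert m.plaque_area_mm2 == 0.0 and m.clamped


class TestSegmentArtery:
    def test_plaque_phantom_measured_close_to_truth(self, plaque_phantom):
        spec, frame, gt = plaque_phantom
        res = segment_artery(frame, (64, 64, spec.radius), spec.mm_per_px)
        err = abs(res.measurement.plaque_area_mm2 - gt.plaque_area_mm2)
        assert err <= 0.15 * gt.plaque_area_mm2

    def test_shadowed_phantom_reconstruction_engaged(self):
        spec = PhantomSpec(seed=3, speckle_sigma=0.3, plaque_bump=(0.0, 10.0),
                           shadow_arc=(240.0, 300.0))
        frame, gt = make_artery_phantom(spec)
        res = segment_artery(frame, (64, 64, spec.radius), spec.mm_per_px)
        assert res.reconstruction_added > 10
        err = abs(res.measurement.plaque_area_mm2 - gt.plaque_area_mm2)
        assert err <= 0.3 * gt.plaque_area_mm2

    def test_user_outline_reported(self, plaque_phantom):
        spec, frame, _ = plaque_phantom
        outline = circle_polygon((64, 64), spec.radius)
        res = segment_artery(frame, (64, 64, spec.radius), spec.mm_per_px,
                             outline=outline)
        assert res.outline_kind == "user"
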