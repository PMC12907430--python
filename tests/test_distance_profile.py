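"""Signed-distance profile: nearest-vertex queries, sign rules, ostium
localization, resampling and differentiation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imlen.distance_profile import (
    build_profile,
    locate_ostium,
    nearest_vertex_distance,
    nearest_vertex_distances,
    points_inside,
    signed_distance,
    signed_distances,
    winding_numbers,
)
from imlen.errors import OstiumNotFoundError, OstiumWarning, SignConventionWarning
from imlen.mesh_io import Centerline, TriangleMesh


def brute_force_nearest(mesh, points):
    """Exhaustive O(V) oracle: first minimal index, same sqrt expression."""
    points = np.atleast_2d(points)
    idx = np.empty(len(points), dtype=np.int64)
    dist = np.empty(len(points))
    for j, p in enumerate(points):
        d2 = np.einsum("ij,ij->i", mesh.vertices - p, mesh.vertices - p)
        idx[j] = int(np.argmin(d2))  # first minimum = smallest index
        dist[j] = np.sqrt(d2[idx[j]])
    return dist, idx


class TestNearestVertex:
    def test_vertex_itself_is_distance_zero(self, icosphere):
        d, i = nearest_vertex_distance(icosphere, icosphere.vertices[7])
        assert d == 0.0
        assert i == 7

    def test_icosphere_centroid_distance_one(self, icosphere):
        d, _ = nearest_vertex_distance(icosphere, [0.0, 0.0, 0.0])
        assert abs(d - 1.0) < 1e-12

    def test_matches_brute_force_exactly(self, coarse_phantom):
        mesh, _, _ = coarse_phantom
        rng = np.random.default_rng(42)
        pts = rng.uniform([-10, -10, -5], [10, 10, 25], size=(200, 3))
        d_fast, i_fast = nearest_vertex_distances(mesh, pts)
        d_ref, i_ref = brute_force_nearest(mesh, pts)
        assert np.array_equal(d_fast, d_ref)
        assert np.array_equal(i_fast, i_ref)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.tuples(
            st.floats(-3, 3, allow_nan=False),
            st.floats(-3, 3, allow_nan=False),
            st.floats(-3, 3, allow_nan=False),
        )
    )
    def test_brute_force_property(self, icosphere, point):
        d, i = nearest_vertex_distance(icosphere, np.array(point))
        d_ref, i_ref = brute_force_nearest(icosphere, np.array(point)[None, :])
        assert d == d_ref[0]
        assert i == i_ref[0]


class TestSign:
    def test_icosphere_centroid_is_interior(self, icosphere):
        assert signed_distance(icosphere, [0.0, 0.0, 0.0]) == pytest.approx(-1.0)

    def test_magnitude_equals_unsigned_distance(self, coarse_phantom):
        mesh, cl, _ = coarse_phantom
        signed = signed_distances(mesh, cl.points)
        unsigned, _ = nearest_vertex_distances(mesh, cl.points)
        assert np.array_equal(np.abs(signed), unsigned)

    def test_convex_hull_membership_oracle(self, icosphere):
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(3)
        pts = rng.uniform(-1.3, 1.3, size=(400, 3))
        hull = ConvexHull(icosphere.vertices)
        margins = pts @ hull.equations[:, :3].T + hull.equations[:, 3]
        strictly_inside = (margins < -1e-9).all(axis=1)
        strictly_outside = (margins > 1e-9).any(axis=1)
        signed = signed_distances(icosphere, pts)
        assert ((signed < 0) == strictly_inside)[strictly_inside | strictly_outside].all()

    def test_ray_parity_agrees_with_winding_number(self, coarse_phantom):
        mesh, _, _ = coarse_phantom
        rng = np.random.default_rng(11)
        pts = rng.uniform([-10, -10, -5], [10, 10, 25], size=(250, 3))
        assert np.array_equal(
            points_inside(mesh, pts), np.abs(winding_numbers(mesh, pts)) > 0.5
        )

    def test_cylinder_wall_offset_is_analytic(self, coarse_phantom):
        # point outside the lateral wall, away from the caps: distance ~ r - R
        mesh, _, _ = coarse_phantom
        r, R = 8.3, 6.0
        d = signed_distance(mesh, [r, 0.0, 10.0])
        assert abs(d - (r - R)) < 0.4  # within half the 0.8 mm edge length

    def test_open_mesh_uses_pseudo_normals_with_warning(self, icosphere):
        open_mesh = TriangleMesh.from_arrays(
            icosphere.vertices, icosphere.faces[:-1]
        )
        with pytest.warns(SignConventionWarning):
            inside = signed_distance(open_mesh, [0.0, 0.0, 0.0])
            outside = signed_distance(open_mesh, [0.0, 0.0, 2.0])
        assert inside < 0 < outside


class TestLocateOstium:
    def test_linear_interpolation_arithmetic(self, icosphere):
        # signed distances [-0.4, -0.1, +0.3] at arcs [0, 0.4, 0.8] -> 0.5 mm
        cl = Centerline.from_points([[0, 0, 0], [0, 0, 0.4], [0, 0, 0.8]])
        d = np.array([-0.4, -0.1, 0.3])
        assert locate_ostium(icosphere, cl, _signed=d) == pytest.approx(0.5)

    def test_all_outside_returns_zero_with_warning(self, icosphere):
        cl = Centerline.from_points([[0, 0, 2], [0, 0, 3]])
        with pytest.warns(OstiumWarning):
            assert locate_ostium(icosphere, cl) == 0.0

    def test_never_exiting_centerline_is_an_error(self, icosphere):
        cl = Centerline.from_points([[0, 0, -0.2], [0, 0, 0.0], [0, 0, 0.2]])
        with pytest.raises(OstiumNotFoundError):
            locate_ostium(icosphere, cl)

    def test_phantom_ostium_recovered_within_one_spacing(self, default_phantom):
        mesh, cl, truth = default_phantom
        offset = locate_ostium(mesh, cl)
        assert abs(offset - truth["ostium_arc_mm"]) <= 0.4


class TestBuildProfile:
    def test_single_linear_segment(self, icosphere, monkeypatch):
        # raw (s, d) = (0, 1.0), (0.4, 2.0): 401 grid points, midpoint 1.5,
        # derivative 2.5 everywhere
        monkeypatch.setattr(
            "imlen.distance_profile.signed_distances",
            lambda mesh, pts: np.array([1.0, 2.0]),
        )
        cl = Centerline.from_points([[0, 0, 0], [0, 0, 0.4]])
        with pytest.warns(OstiumWarning):
            prof = build_profile(icosphere, cl, spacing_mm=0.001)
        assert len(prof) == 401
        assert prof.dist[200] == pytest.approx(1.5)
        assert np.allclose(prof.deriv, 2.5, atol=1e-9)

    def test_constant_distance_has_zero_derivative(self, icosphere, monkeypatch):
        monkeypatch.setattr(
            "imlen.distance_profile.signed_distances",
            lambda mesh, pts: np.full(len(np.atleast_2d(pts)), 3.0),
        )
        cl = Centerline.from_points([[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        with pytest.warns(OstiumWarning):
            prof = build_profile(icosphere, cl, spacing_mm=0.01)
        assert np.allclose(prof.deriv, 0.0, atol=1e-12)

    def test_resampled_distance_reproduces_raw_values(self, coarse_phantom):
        mesh, cl, _ = coarse_phantom
        prof = build_profile(mesh, cl, spacing_mm=0.01)
        d = signed_distances(mesh, cl.points)
        s = cl.cum_arc - prof.ostium_offset_mm
        keep = (s >= 0) & (s <= prof.arc[-1])
        nearest = np.clip(
            np.rint(s[keep] / prof.spacing_mm).astype(int), 0, len(prof) - 1
        )
        # within one grid step of local variation
        local_slope = np.abs(np.gradient(d[keep], s[keep]))
        tol = (local_slope + 1.0) * prof.spacing_mm
        assert (np.abs(prof.dist[nearest] - d[keep]) <= tol).all()

    def test_derivative_integrates_back_to_distance(self, default_phantom):
        mesh, cl, _ = default_phantom
        prof = build_profile(mesh, cl, spacing_mm=0.001)
        integral = np.trapezoid(prof.deriv, prof.arc)
        assert integral == pytest.approx(prof.dist[-1] - prof.dist[0], abs=0.01)

    def test_phantom_regime_slopes_match_design(self, default_phantom, default_spec):
        mesh, cl, truth = default_phantom
        prof = build_profile(mesh, cl, spacing_mm=0.001)
        L, b = default_spec.im_length_mm, default_spec.slope_b
        rate = (default_spec.slope_c - b) / default_spec.departure_mm
        in_b = (prof.arc > 1.5) & (prof.arc < L - 0.5)
        assert prof.deriv[in_b].mean() == pytest.approx(b, abs=0.1 * max(b, 0.05))
        in_c = (prof.arc > L + 2) & (prof.arc < L + 6)
        expected = b + rate * (prof.arc[in_c].mean() - L)
        assert prof.deriv[in_c].mean() == pytest.approx(expected, rel=0.1)
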