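"""Discrete curvature/torsion estimators against closed-form geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from vesselmorph.errors import DegenerateGeometryError, ParameterError
from vesselmorph.geometry import (arc_length_weights, curvature_profile,
                                  path_geometry, resample_path,
                                  torsion_profile)


def helix(r, c, dt, n):
    t = np.arange(n) * dt
    return np.column_stack([r * np.cos(t), r * np.sin(t), c * t])


class TestResample:
    def test_straight_segment_uniform_spacing(self):
        pts = np.array([[0, 0, 0], [10, 0, 0]], float)
        new_pts, new_r = resample_path(pts, np.array([4.0, 4.0]), step=2.5)
        assert np.allclose(new_pts[:, 0], [0, 2.5, 5, 7.5, 10])
        assert np.allclose(new_r, 4.0)

    def test_radii_linearly_interpolated(self):
        pts = np.array([[0, 0, 0], [10, 0, 0]], float)
        _, new_r = resample_path(pts, np.array([3.0, 5.0]), step=2.5)
        assert np.allclose(new_r, [3, 3.5, 4, 4.5, 5])

    def test_arc_length_preserved_within_one_step(self):
        # smooth curve sampled below its curvature radius
        pts = helix(27.0, 5.0, 1 / 27.0, 180)
        orig = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        new_pts, _ = resample_path(pts, np.ones(len(pts)), step=0.7)
        new = np.linalg.norm(np.diff(new_pts, axis=0), axis=1).sum()
        assert abs(new - orig) < 0.7
        assert np.allclose(new_pts[0], pts[0]) and np.allclose(new_pts[-1], pts[-1])

    def test_endpoints_preserved_on_jagged_path(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(size=(50, 3)), axis=0)
        new_pts, _ = resample_path(pts, np.ones(50), step=0.7)
        assert np.allclose(new_pts[0], pts[0]) and np.allclose(new_pts[-1], pts[-1])

    def test_circle_resampled_points_stay_near_circle(self):
        # chord-vs-arc bound: deviation <= (1 - cos(theta/2)) * R, theta = 1/27
        pts = helix(27.0, 0.0, 1 / 27.0, 180)
        new_pts, _ = resample_path(pts, np.ones(len(pts)), step=1.0)
        d = np.linalg.norm(new_pts[:, :2], axis=1)
        assert np.all(np.abs(d - 27.0) <= 27.0 * (1 - np.cos(0.5 / 27)) + 1e-9)

    def test_nonpositive_step_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0]], float)
        with pytest.raises(ParameterError):
            resample_path(pts, np.ones(2), step=0.0)


class TestCurvature:
    def test_unit_circumradius_triple(self):
        kappa = curvature_profile(np.array([[0, 0, 0], [1, 1, 0], [2, 0, 0]],
                                           float))
        assert kappa == pytest.approx([1.0])

    def test_collinear_points_have_zero_curvature(self):
        pts = np.column_stack([np.arange(5), 2 * np.arange(5), np.zeros(5)])
        assert np.allclose(curvature_profile(pts), 0.0)

    @pytest.mark.parametrize("radius", [27.0, 48.0, 3.5])
    def test_concyclic_triples_give_reciprocal_radius(self, radius, rng):
        # Menger curvature is exact for circle samples at any spacing
        theta = np.sort(rng.uniform(0, 2 * np.pi, 3))
        pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                               np.zeros(3)])
        kappa = curvature_profile(pts)
        assert kappa[0] == pytest.approx(1 / radius, rel=1e-12)

    def test_fewer_than_three_points_empty_profile(self):
        assert curvature_profile(np.array([[0, 0, 0], [1, 0, 0]], float)).size == 0

    def test_coincident_points_rejected(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            curvature_profile(pts)


class TestTorsion:
    def test_planar_zigzag_has_zero_torsion(self):
        pts = np.array([[0, 0, 0], [1, 1, 0], [2, 0, 0], [3, 1, 0], [4, 0, 0]],
                       float)
        assert np.allclose(torsion_profile(pts), 0.0)

    def test_helix_closed_forms_within_one_percent(self):
        # kappa -> r/(r^2+c^2), tau -> c/(r^2+c^2)
        pts = helix(2.0, 1.0, 0.05, 400)
        kappa = curvature_profile(pts).mean()
        tau = torsion_profile(pts).mean()
        assert kappa == pytest.approx(0.4, rel=0.01)
        assert tau == pytest.approx(0.2, rel=0.01)

    def test_estimates_converge_second_order(self):
        errs = []
        for dt in (0.1, 0.05, 0.025):
            pts = helix(2.0, 1.0, dt, int(20 / dt))
            errs.append(abs(torsion_profile(pts).mean() - 0.2))
        assert errs[0] / errs[1] > 3.0 and errs[1] / errs[2] > 3.0

    def test_mirror_reflection_negates_torsion(self):
        pts = helix(2.0, 1.0, 0.05, 200)
        tau = torsion_profile(pts)
        mirrored = pts.copy()
        mirrored[:, 2] *= -1
        assert np.allclose(torsion_profile(mirrored), -tau)

    def test_collinear_triple_inside_quadruple_gives_zero(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 1]], float)
        assert torsion_profile(pts) == pytest.approx([0.0])

    def test_fewer_than_four_points_empty_profile(self):
        pts = np.array([[0, 0, 0], [1, 1, 0], [2, 0, 0]], float)
        assert torsion_profile(pts).size == 0


class TestWeights:
    def test_voronoi_weights_example(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [6, 0, 0]], float)
        assert np.allclose(arc_length_weights(pts), [1, 3, 2])

    def test_two_points_split_the_chord(self):
        pts = np.array([[0, 0, 0], [10, 0, 0]], float)
        assert np.allclose(arc_length_weights(pts), [5, 5])

    def test_weights_sum_to_arc_length_closed_and_open(self, rng):
        pts = np.cumsum(rng.normal(size=(30, 3)), axis=0)
        open_len = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert arc_length_weights(pts).sum() == pytest.approx(open_len)
        closed_len = open_len + np.linalg.norm(pts[-1] - pts[0])
        assert arc_length_weights(pts, closed=True).sum() == \
            pytest.approx(closed_len)


class TestInvariances:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10**6), scale=st.floats(0.1, 50))
    def test_scale_covariance(self, seed, scale):
        """Scaling coordinates by a scales kappa and tau by 1/a."""
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(size=(12, 3)), axis=0)
        k1, t1 = curvature_profile(pts), torsion_profile(pts)
        k2, t2 = curvature_profile(pts * scale), torsion_profile(pts * scale)
        assert np.allclose(k2 * scale, k1, rtol=1e-8, atol=1e-12)
        assert np.allclose(t2 * scale, t1, rtol=1e-8, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10**6))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(size=(12, 3)), axis=0)
        rot = Rotation.random(rng=np.random.default_rng(seed + 1)).as_matrix()
        moved = pts @ rot.T + rng.uniform(-50, 50, 3)
        assert np.allclose(curvature_profile(moved), curvature_profile(pts),
                           rtol=1e-8, atol=1e-10)
        assert np.allclose(torsion_profile(moved), torsion_profile(pts),
                           rtol=1e-8, atol=1e-10)


class TestPathGeometry:
    def test_profile_lengths_and_weight_sum(self, rng):
        pts = np.cumsum(rng.normal(size=(40, 3)), axis=0) * 3
        g = path_geometry(pts, np.full(40, 4.0), resample_step=1.0)
        n = len(g.points)
        assert len(g.curvature) == n - 2 and len(g.torsion) == n - 3
        assert g.weights.sum() == pytest.approx(g.arc_length)
        assert len(g.curvature_weights) == n - 2
        assert len(g.torsion_weights) == n - 3

    def test_closed_circle_all_points_interior(self):
        n = 170
        theta = 2 * np.pi * np.arange(n + 1) / n
        pts = np.column_stack([27 * np.cos(theta), 27 * np.sin(theta),
                               np.zeros(n + 1)])
        g = path_geometry(pts, np.full(n + 1, 4.0), closed=True,
                          resample_step=None)
        assert len(g.curvature) == len(g.points) == n
        assert np.allclose(g.curvature, 1 / 27.0, rtol=1e-9)
        assert g.weights.sum() == pytest.approx(g.arc_length)

    def test_raw_mode_skips_resampling(self):
        pts = np.array([[0, 0, 0], [1, 1, 0], [2, 0, 0]], float)
        g = path_geometry(pts, np.full(3, 2.0), resample_step=None)
        assert len(g.points) == 3
        assert g.curvature == pytest.approx([1.0])
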