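"""Centerline construction: constraints, landmarks, frames, radius law."""

import math

import numpy as np
import pytest

from aortagen.centerline import (Centerline, branch_stations, build_centerline,
                                 radius_profile)
from aortagen.errors import InfeasibleGeometryError, ParameterError


class TestLandmarks:
    def test_station_sums_type_i(self, type_i_params):
        cl = build_centerline(type_i_params)
        st = branch_stations(type_i_params, cl)
        assert st["BA"].arclen == pytest.approx(7.62)
        assert st["LCA"].arclen == pytest.approx(7.62 + 1.68)
        assert st["LSA"].arclen == pytest.approx(12.74)

    def test_station_sums_type_ii(self, type_ii_params):
        cl = build_centerline(type_ii_params)
        st = branch_stations(type_ii_params, cl)
        assert st["trunk"].arclen == pytest.approx(7.62)
        assert st["LSA"].arclen == pytest.approx(10.32)

    def test_zero_spacing_makes_stations_coincide(self, type_i_params):
        p = type_i_params.with_overrides(d1=1e-9)
        cl = build_centerline(p)
        st = branch_stations(p, cl)
        assert st["BA"].arclen == pytest.approx(st["LCA"].arclen)

    def test_station_beyond_arch_end_raises(self, type_i_params):
        p = type_i_params.with_overrides(d2=30.0)
        with pytest.raises(InfeasibleGeometryError, match="beyond the arch"):
            build_centerline(p)

    def test_stations_snap_onto_samples(self, type_i_params):
        cl = build_centerline(type_i_params, resolution=5.0)
        for name in ("BA", "LCA", "LSA", "arch_start", "mid_descending"):
            s = cl.landmarks[name]
            assert cl.arclen[cl.index_at(s)] == pytest.approx(s, abs=1e-12)


class TestConstraints:
    def test_arch_spans_height_and_width(self, type_i_params):
        cl = build_centerline(type_i_params)
        pa = cl.points[cl.index_at(cl.landmarks["arch_start"])]
        pe = cl.points[cl.index_at(cl.landmarks["arch_end"])]
        apex = cl.points[cl.index_at(cl.landmarks["arch_apex"])]
        assert np.linalg.norm((pe - pa)[:2]) == pytest.approx(7.95, rel=2e-3)
        assert apex[2] - pa[2] == pytest.approx(4.06, rel=2e-3)

    def test_transverse_projection_is_circular_arc(self, type_i_params):
        cl = build_centerline(type_i_params)
        mask = ((cl.arclen >= cl.landmarks["arch_start"])
                & (cl.arclen <= cl.landmarks["arch_end"]))
        xy = cl.points[mask][:, :2]
        A = np.column_stack([2 * xy, np.ones(len(xy))])
        sol, *_ = np.linalg.lstsq(A, (xy ** 2).sum(axis=1), rcond=None)
        R = math.sqrt(sol[2] + sol[0] ** 2 + sol[1] ** 2)
        assert R == pytest.approx(type_i_params.R, rel=1e-3)

    def test_degenerate_angles_give_vertical_planar_geometry(self, type_i_params):
        """With all beta angles zero (and no transverse bend) the arch is
        planar in the parasagittal plane and the descending limb vertical."""
        p = type_i_params.with_overrides(beta1=1e-12, beta2=1e-12, beta3=1e-12,
                                         R=1e6)
        cl = build_centerline(p)
        assert np.allclose(cl.tangent[-1], [0, 0, -1], atol=1e-6)
        mask = ((cl.arclen >= cl.landmarks["arch_start"])
                & (cl.arclen <= cl.landmarks["arch_end"]))
        assert np.ptp(cl.points[mask][:, 0]) < 1e-4  # planar: no x excursion

    def test_descending_tilt_and_twist(self, type_i_params):
        cl = build_centerline(type_i_params)
        d = cl.tangent[-1]
        beta1 = math.degrees(math.acos(-d[2]))
        beta2 = math.degrees(math.atan2(d[0], -d[1]))
        assert beta1 == pytest.approx(10.0, abs=1e-6)
        assert beta2 == pytest.approx(10.0, abs=1e-6)

    def test_scale_equivariance(self, type_i_params):
        """Doubling all lengths doubles every landmark arc length."""
        cl1 = build_centerline(type_i_params)
        cl2 = build_centerline(type_i_params.scaled(2.0))
        for name, s in cl1.landmarks.items():
            if s > 0:
                assert cl2.landmarks[name] / s == pytest.approx(2.0, rel=1e-9)

    def test_infeasible_bend_radius(self, type_i_params):
        with pytest.raises(InfeasibleGeometryError, match="R"):
            build_centerline(type_i_params.with_overrides(R=2.0))


class TestArcLength:
    def test_ascending_segment_length_converges(self, type_i_params):
        """Chord-summed arc length matches the analytic segment length and
        the error at least halves under refinement."""
        errs = []
        for res in (4.0, 8.0):
            cl = build_centerline(type_i_params, resolution=res)
            i0 = cl.index_at(cl.landmarks["arch_start"])
            i1 = cl.index_at(cl.landmarks["arch_end"])
            chord = np.linalg.norm(np.diff(cl.points[i0:i1 + 1], axis=0),
                                   axis=1).sum()
            analytic = cl.landmarks["arch_end"] - cl.landmarks["arch_start"]
            errs.append(abs(chord - analytic) / analytic)
        assert errs[0] < 1e-3
        assert errs[1] <= errs[0] / 2


class TestFrames:
    def test_orthonormal_and_flip_free(self, type_i_params):
        cl = build_centerline(type_i_params)
        fr = cl.frames()
        assert np.abs(np.einsum("ij,ij->i", fr.tangent, fr.normal)).max() < 1e-9
        assert np.abs(np.linalg.norm(fr.normal, axis=1) - 1).max() < 1e-9
        assert np.einsum("ij,ij->i", fr.normal[1:], fr.normal[:-1]).min() > 0

    def test_resolution_independent(self, type_i_params):
        """Frames at shared stations agree between samplings to 1e-6."""
        cl1 = build_centerline(type_i_params, resolution=4.0)
        cl2 = build_centerline(type_i_params, resolution=8.0)
        s = np.array([cl1.landmarks[k] for k in ("arch_start", "arch_apex",
                                                 "BA", "LSA", "outlet")])
        f1, f2 = cl1.frames(s), cl2.frames(s)
        assert np.abs(f1.normal - f2.normal).max() < 1e-6
        assert np.abs(f1.tangent - f2.tangent).max() < 1e-6


class TestRadiusProfile:
    def test_knot_radii(self, type_i_params):
        cl = build_centerline(type_i_params)
        rp = radius_profile(type_i_params, cl)
        assert rp(0.0) == pytest.approx(3.17 / 2, abs=1e-9)
        assert rp(cl.landmarks["arch_apex"]) == pytest.approx(2.65 / 2, abs=1e-9)
        assert rp(cl.landmarks["mid_descending"]) == pytest.approx(2.5 / 2, abs=1e-9)

    def test_no_overshoot_between_knots(self, type_i_params):
        cl = build_centerline(type_i_params)
        rp = radius_profile(type_i_params, cl)
        ks, kr = rp.knots_s, rp.knots_r
        for i in range(len(ks) - 1):
            s = np.linspace(ks[i], ks[i + 1], 200)
            r = rp(s)
            lo, hi = min(kr[i], kr[i + 1]), max(kr[i], kr[i + 1])
            assert np.all(r >= lo - 1e-12) and np.all(r <= hi + 1e-12)

    def test_missing_landmark_raises(self, type_i_params):
        cl = build_centerline(type_i_params)
        bare = Centerline.from_points(cl.points)
        with pytest.raises(ParameterError, match="landmark"):
            radius_profile(type_i_params, bare)


def test_from_points_polyline():
    pts = np.column_stack([np.zeros(30), np.zeros(30), np.linspace(0, 5, 30)])
    cl = Centerline.from_points(pts)
    assert cl.length == pytest.approx(5.0)
    assert np.allclose(cl.tangent, [0, 0, 1], atol=1e-12)
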