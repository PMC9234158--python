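"""Bifurcation matching, registration, interpolation and lumen exchange."""
import numpy as np
import pytest

import fusionffr as ff
from fusionffr.fuse import FusionError
from tests.conftest import circle_points


def marker_stack(z_positions, directions=None, length_mm=30.0, radius=1.5,
                 modality=ff.Modality.CTA):
    n = int(length_mm / 0.25) + 1
    contours = [ff.Contour(circle_points(r=radius, n=64), k)
                for k in range(n)]
    dirs = directions or [0.0] * len(z_positions)
    markers = [ff.BifurcationMarker(z, d, 1.0)
               for z, d in zip(z_positions, dirs)]
    return ff.ContourStack(modality=modality, contours=contours, spacing=0.25,
                           bifurcations=markers)


class TestMatchBifurcations:
    def test_single_pair(self):
        pairs, uc, uo = ff.match_bifurcations(marker_stack([10.0]),
                                              marker_stack([4.0]))
        assert len(pairs) == 1 and not uc and not uo

    def test_two_pairs_exact_offset(self):
        pairs, *_ = ff.match_bifurcations(marker_stack([10.0, 25.0]),
                                          marker_stack([4.0, 19.0]))
        assert [(c.z_mm, o.z_mm) for c, o in pairs] == [(10.0, 4.0),
                                                        (25.0, 19.0)]
        reg = ff.register(marker_stack([10.0, 25.0]),
                          marker_stack([4.0, 19.0]))
        assert reg.longitudinal_offset_mm == pytest.approx(6.0)

    def test_extra_oct_marker_flagged_unmatched(self):
        pairs, uc, uo = ff.match_bifurcations(
            marker_stack([10.0, 25.0]), marker_stack([4.0, 12.0, 19.0]))
        assert [(c.z_mm, o.z_mm) for c, o in pairs] == [(10.0, 4.0),
                                                        (25.0, 19.0)]
        assert [m.z_mm for m in uo] == [12.0]

    def test_no_markers_rejected(self):
        with pytest.raises(FusionError, match="bifurcation"):
            ff.match_bifurcations(marker_stack([]), marker_stack([4.0]))


class TestRegister:
    def test_identical_stacks_identity(self):
        a = marker_stack([10.0], [45.0])
        reg = ff.register(a, marker_stack([10.0], [45.0]))
        assert reg.longitudinal_offset_mm == 0.0
        assert reg.rotation_at(10.0) == pytest.approx(0.0)

    def test_rotation_interpolated_between_landmarks(self):
        cta = marker_stack([10.0, 20.0], [10.0, 20.0])
        oct_stack = marker_stack([10.0, 20.0], [0.0, 0.0])
        reg = ff.register(cta, oct_stack)
        assert reg.rotation_at(15.0) == pytest.approx(15.0)
        # constant extrapolation beyond the outermost landmarks
        assert reg.rotation_at(2.0) == pytest.approx(10.0)
        assert reg.rotation_at(28.0) == pytest.approx(20.0)

    def test_rotation_wrapped_to_half_circle(self):
        reg = ff.register(marker_stack([10.0], [10.0]),
                          marker_stack([10.0], [350.0]))
        assert reg.rotation_at(10.0) == pytest.approx(20.0)

    def test_large_rotation_disagreement_warns(self):
        cta = marker_stack([10.0, 20.0], [0.0, 130.0])
        oct_stack = marker_stack([10.0, 20.0], [0.0, 0.0])
        with pytest.warns(UserWarning, match="90"):
            ff.register(cta, oct_stack)

    def test_recovers_synthetic_rotation_and_offset(self):
        geom = ff.generate_vessel(ff.VesselSpec(
            length_mm=20, base_radius_mm=1.5,
            bifurcations=[(4.0, 90.0, 1.0), (16.0, 200.0, 1.0)]))
        cta, oct_stack = ff.image_vessel(geom, ff.ImagingSpec(
            oct_rotation_deg=30.0, oct_offset_mm=2.0))
        reg = ff.register(cta, oct_stack)
        assert reg.longitudinal_offset_mm == pytest.approx(2.0, abs=0.1)
        assert reg.rotation_at(10.0) == pytest.approx(30.0, abs=0.5)

    def test_parameter_recovery_randomized(self):
        """Random rotation/offset with 2% radial noise: recovered within
        5 deg and half a CTA frame in at least 19 of 20 cases."""
        geom = ff.generate_vessel(ff.VesselSpec(
            length_mm=20, base_radius_mm=1.5, stenosis=(10.0, 60.0, 6.0),
            bifurcations=[(4.0, 90.0, 1.0), (16.0, 200.0, 1.0)]))
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(20):
            rot = rng.uniform(-180.0, 180.0)
            off = max(rng.uniform(-5.0, 5.0), 0.0)
            cta, oct_stack = ff.image_vessel(geom, ff.ImagingSpec(
                oct_rotation_deg=rot, oct_offset_mm=off,
                cta_radial_noise_sd=0.02, oct_radial_noise_sd=0.02,
                seed=int(rng.integers(1 << 31))))
            reg = ff.register(cta, oct_stack)
            rerr = np.abs((np.asarray(reg.rotation_knots_deg) - rot + 180)
                          % 360 - 180).max()
            oerr = abs(reg.longitudinal_offset_mm - off)
            hits += (rerr < 5.0) and (oerr < 0.125)
        assert hits >= 19


class TestInterpolateToCtaSpacing:
    def _taper_stack(self):
        # linear radius taper 2.0 -> 1.0 mm over 10 mm at OCT spacing
        contours = []
        for j, z in enumerate(np.arange(0, 10 + 1e-9, 0.2)):
            r = 2.0 - 0.1 * z
            contours.append(ff.Contour(circle_points(r=r, n=64), j))
        return ff.ContourStack(modality=ff.Modality.OCT, contours=contours,
                               spacing=0.2,
                               bifurcations=[ff.BifurcationMarker(5.0, 0, 1)])

    def test_contour_reproduced_at_knot(self):
        stack = self._taper_stack()
        out = ff.interpolate_oct_to_cta_spacing(stack, 0.25)
        # z = 1.0 mm is both an OCT frame (j=5) and a target frame (k=4)
        np.testing.assert_allclose(out.contours[4].points,
                                   stack.contours[5].points, atol=1e-9)

    def test_linear_taper_preserved(self):
        out = ff.interpolate_oct_to_cta_spacing(self._taper_stack(), 0.25)
        for k, c in enumerate(out.contours):
            r = np.hypot(*(c.points - c.centroid).T)
            np.testing.assert_allclose(r, 2.0 - 0.1 * (k * 0.25), atol=1e-6)

    def test_interpolated_areas_bracketed_by_neighbours(self):
        stack = self._taper_stack()
        out = ff.interpolate_oct_to_cta_spacing(stack, 0.25)
        z_oct = stack.z_mm
        areas_oct = stack.areas
        for k, c in enumerate(out.contours):
            z = k * 0.25
            j = min(int(z / 0.2), len(z_oct) - 2)
            lo = min(areas_oct[j], areas_oct[j + 1]) - 1e-12
            hi = max(areas_oct[j], areas_oct[j + 1]) + 1e-12
            assert lo <= c.area <= hi

    def test_positions_outside_extent_excluded(self):
        out = ff.interpolate_oct_to_cta_spacing(
            self._taper_stack(), 0.25, target_z_mm=np.array([-1.0, 0.0, 9.0,
                                                             20.0]))
        assert out.n_frames == 2


class TestFuse:
    def test_full_coverage_exchanges_all_lumens(self, paired_stacks):
        geom, cta, oct_stack = paired_stacks
        model = ff.fuse(cta, oct_stack)
        cov = model.coverage
        # OCT covers [2, 20] mm of the 20 mm vessel
        assert cov.sum() >= 70
        fused_areas = model.stack.areas[cov]
        truth = np.array([geom.area(z) for z in cta.z_mm[cov]])
        np.testing.assert_allclose(fused_areas, truth, rtol=0.01)

    def test_fusion_restores_mla_despite_cta_bias(self, paired_stacks):
        geom, cta, oct_stack = paired_stacks
        model = ff.fuse(cta, oct_stack)
        assert model.stack.minimal_lumen_area() == pytest.approx(
            geom.mla_mm2, rel=0.02)
        # un-fused CTA model carries the full squared radial bias
        assert cta.minimal_lumen_area() == pytest.approx(
            geom.mla_mm2 * 1.44, rel=0.02)

    def test_identical_modalities_leave_cta_untouched(self):
        geom = ff.generate_vessel(ff.VesselSpec(
            length_mm=20, base_radius_mm=1.5,
            bifurcations=[(4.0, 90.0, 1.0)]))
        cta, oct_stack = ff.image_vessel(geom, ff.ImagingSpec())
        model = ff.fuse(cta, oct_stack)
        outside = ~model.coverage
        for k in np.where(outside)[0]:
            np.testing.assert_array_equal(model.stack.contours[k].points,
                                          cta.contours[k].points)

    def test_junction_area_continuity(self, paired_stacks):
        _, cta, oct_stack = paired_stacks
        model = ff.fuse(cta, oct_stack)
        k = int(np.where(model.coverage)[0][0])
        if k > 0:
            a = model.stack.areas
            assert abs(a[k] - a[k - 1]) / a[k - 1] < 0.05

    def test_mla_invariant_to_initial_rotation(self):
        geom = ff.generate_vessel(ff.VesselSpec(
            length_mm=20, base_radius_mm=1.5, stenosis=(10.0, 60.0, 6.0),
            bifurcations=[(4.0, 90.0, 1.0), (16.0, 200.0, 1.0)]))
        mlas = []
        for rot in (0.0, 90.0, 180.0):
            cta, oct_stack = ff.image_vessel(geom, ff.ImagingSpec(
                oct_rotation_deg=rot, oct_offset_mm=2.0,
                cta_radial_bias=1.2))
            mlas.append(ff.fuse(cta, oct_stack).stack.minimal_lumen_area())
        assert max(mlas) - min(mlas) < 1e-6

    def test_ring_centroids_on_cta_centerline(self, paired_stacks):
        _, cta, oct_stack = paired_stacks
        model = ff.fuse(cta, oct_stack)
        centroids = model.rings.mean(axis=1)
        dev = np.linalg.norm(
            centroids - cta.centerline.points[:len(centroids)], axis=1)
        assert dev.max() < 1e-6

    def test_insufficient_coverage_rejected(self):
        geom = ff.generate_vessel(ff.VesselSpec(
            length_mm=20, base_radius_mm=1.5,
            bifurcations=[(4.0, 90.0, 1.0)]))
        cta, oct_stack = ff.image_vessel(geom, ff.ImagingSpec(
            oct_offset_mm=19.9))
        with pytest.raises(FusionError):
            ff.fuse(cta, oct_stack)
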