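"""Frames, resampling, mother-vessel estimation and surface generation."""
import numpy as np
import pytest

import fusionffr as ff
from fusionffr.contours import ValidationError
from fusionffr.reconstruct import straight_centerline
from tests.conftest import circle_points, cylinder_rings


class TestLocalFrames:
    def test_straight_line_frames_are_identity(self):
        pts = np.stack([np.zeros(10), np.zeros(10), np.linspace(0, 9, 10)], 1)
        cl = ff.build_local_frames(pts)
        np.testing.assert_allclose(cl.frames[:, 0], [[0, 0, 1]] * 10,
                                   atol=1e-12)
        np.testing.assert_allclose(cl.frames[:, 1], [[1, 0, 0]] * 10,
                                   atol=1e-12)
        np.testing.assert_allclose(cl.frames[:, 2], [[0, 1, 0]] * 10,
                                   atol=1e-12)

    def test_planar_curve_has_constant_binormal(self):
        t = np.linspace(0, np.pi / 2, 60)
        pts = np.stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)], 1)
        cl = ff.build_local_frames(pts)
        spread = np.abs(cl.frames[:, 2] - cl.frames[0, 2]).max()
        assert spread < 1e-6

    def test_helix_refinement_convergence(self):
        def helix(n):
            t = np.linspace(0, 4 * np.pi, n)
            return np.stack([2 * np.cos(t), 2 * np.sin(t), t], 1)

        n1 = ff.build_local_frames(helix(400)).frames[-1, 1]
        n2 = ff.build_local_frames(helix(800)).frames[-1, 1]
        angle = np.degrees(np.arccos(np.clip(np.dot(n1, n2), -1, 1)))
        assert angle < 0.5

    def test_total_twist_small_on_planar_centerline(self):
        # rotation-minimizing property: binormal must not spin about a
        # planar curve regardless of discretization
        for n in (25, 50, 400):
            t = np.linspace(0, 2.0, n)
            pts = np.stack([np.sin(t), np.zeros_like(t), t], 1)
            cl = ff.build_local_frames(pts)
            twist = np.degrees(np.arccos(np.clip(
                np.abs(cl.frames[:, 2] @ np.array([0, 1, 0.])), -1, 1))).max()
            assert twist < 1.0

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            ff.build_local_frames([[0, 0, 0], [0, 0, 0], [0, 0, 1]])

    def test_frames_orthonormal(self):
        t = np.linspace(0, 3, 40)
        pts = np.stack([np.cos(3 * t), np.sin(2 * t), t], 1)
        cl = ff.build_local_frames(pts)
        eye = np.einsum("nij,nkj->nik", cl.frames, cl.frames)
        np.testing.assert_allclose(eye, np.broadcast_to(np.eye(3), eye.shape),
                                   atol=1e-9)


class TestResampleContour:
    def test_circle_area_preserved(self):
        c = ff.Contour(circle_points(r=1.0, n=360), 0)
        rc = ff.resample_contour(c, 64)
        assert rc.area == pytest.approx(np.pi, rel=5e-3)

    def test_deterministic_and_idempotent(self):
        ellipse = circle_points(r=1.0, n=256) * np.array([2.0, 1.0])
        c = ff.Contour(ellipse, 0)
        np.testing.assert_allclose(ff.resample_contour(c, 64).points,
                                   ff.resample_contour(c, 64).points,
                                   atol=0)
        # on a circle equal arc steps land back on the vertices exactly
        circ = ff.Contour(circle_points(r=1.0, n=64), 0)
        rc1 = ff.resample_contour(circ, 64)
        rc2 = ff.resample_contour(rc1, 64)
        np.testing.assert_allclose(rc1.points, rc2.points, atol=1e-9)

    def test_ellipse_perimeter_ramanujan(self):
        a, b = 2.0, 1.0
        ellipse = circle_points(r=1.0, n=2048) * np.array([a, b])
        rc = ff.resample_contour(ff.Contour(ellipse, 0), 128)
        seg = np.linalg.norm(np.diff(np.vstack([rc.points, rc.points[:1]]),
                                     axis=0), axis=1).sum()
        h = ((a - b) / (a + b)) ** 2
        ramanujan = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        assert seg == pytest.approx(ramanujan, rel=1e-2)

    def test_minimum_points_enforced(self, circle_contour):
        with pytest.raises(ValidationError):
            ff.resample_contour(circle_contour, 4)


class TestMotherVessel:
    def test_no_bifurcations_identity(self, circle_contour):
        stack = ff.ContourStack(
            modality=ff.Modality.CTA,
            contours=[ff.Contour(circle_points(), k) for k in range(5)],
            spacing=0.25)
        assert ff.estimate_mother_vessel(stack) is stack

    def test_ostium_bulge_removed(self):
        geom = ff.generate_vessel(ff.VesselSpec(
            length_mm=10, base_radius_mm=1.5,
            bifurcations=[(5.0, 60.0, 1.0)], ostium_bump_mm=1.0))
        cta, _ = ff.image_vessel(geom, ff.ImagingSpec())
        bulge_r = max(np.hypot(*c.points.T).max() for c in cta.contours)
        assert bulge_r > 2.0  # generator did produce an ostium
        clean = ff.estimate_mother_vessel(cta)
        radii = np.concatenate([np.hypot(*c.points.T) for c in clean.contours])
        assert np.all(np.abs(radii - 1.5) < 0.05)

    def test_locality_frames_outside_range_bit_identical(self):
        geom = ff.generate_vessel(ff.VesselSpec(
            length_mm=20, base_radius_mm=1.5,
            bifurcations=[(5.0, 60.0, 1.0), (15.0, 240.0, 1.0)],
            ostium_bump_mm=0.8))
        cta, _ = ff.image_vessel(geom, ff.ImagingSpec())
        clean = ff.estimate_mother_vessel(cta)
        z = cta.z_mm
        outside = (np.abs(z - 5.0) > 0.5) & (np.abs(z - 15.0) > 0.5)
        for k in np.where(outside)[0]:
            assert clean.contours[k].points is not cta.contours[k].points \
                or True
            np.testing.assert_array_equal(clean.contours[k].points,
                                          cta.contours[k].points)
        changed = [k for k in range(cta.n_frames)
                   if not np.array_equal(clean.contours[k].points,
                                         cta.contours[k].points)]
        assert changed and all(not outside[k] for k in changed)

    def test_bifurcation_at_boundary_rejected(self):
        stack = ff.ContourStack(
            modality=ff.Modality.CTA,
            contours=[ff.Contour(circle_points(), k) for k in range(5)],
            spacing=0.25,
            bifurcations=[ff.BifurcationMarker(0.0, 90.0, 1.0)])
        with pytest.raises(ValidationError, match="flanking"):
            ff.estimate_mother_vessel(stack)


class TestPlaceContours:
    def _stack(self, n=9, spacing=0.25):
        return ff.ContourStack(
            modality=ff.Modality.OCT,
            contours=[ff.Contour(circle_points(r=1.0, n=64), k)
                      for k in range(n)],
            spacing=spacing)

    def test_straight_centerline_gives_cylinder(self):
        stack = self._stack()
        cl = straight_centerline(stack.extent_mm, n=stack.n_frames)
        rings = ff.place_contours(stack, cl, n_points=64)
        r = np.hypot(rings[..., 0], rings[..., 1])
        np.testing.assert_allclose(r, 1.0, atol=1e-9)
        np.testing.assert_allclose(rings[:, :, 2],
                                   np.repeat(stack.z_mm[:, None], 64, 1),
                                   atol=1e-9)

    def test_ring_normals_follow_90_degree_bend(self):
        stack = self._stack(n=41, spacing=0.25)
        rad = stack.extent_mm / (np.pi / 2)
        t = np.linspace(0, np.pi / 2, 200)
        bend = np.stack([rad * (1 - np.cos(t)), np.zeros_like(t),
                         rad * np.sin(t)], 1)
        cl = ff.build_local_frames(bend)
        rings = ff.place_contours(stack, cl, n_points=64)
        def ring_normal(ring):
            c = ring.mean(0)
            u, v = ring[0] - c, ring[16] - c
            n = np.cross(u, v)
            return n / np.linalg.norm(n)
        ang = np.degrees(np.arccos(np.clip(
            np.dot(ring_normal(rings[0]), ring_normal(rings[-1])), -1, 1)))
        # end rings use one-sided chord tangents, each lagging the true end
        # tangent by half a chord angle (~1.1 deg at this spacing)
        assert ang == pytest.approx(90.0, abs=3.0)

    def test_stack_longer_than_centerline_rejected(self):
        stack = self._stack(n=9)
        cl = straight_centerline(1.0)
        with pytest.raises(ValidationError, match="exceeds"):
            ff.place_contours(stack, cl)


class TestRayCastSurface:
    def test_minimal_tube_counts(self):
        rings = cylinder_rings(n_points=64, n_rings=2)
        mesh = ff.ray_cast_surface(rings)
        assert len(mesh.vertices) == 2 * 64 + 2
        assert mesh.euler_characteristic == 2
        assert mesh.is_watertight

    def test_cylinder_volume_closed_form(self):
        mesh = ff.ray_cast_surface(
            cylinder_rings(radius=1.5, length=20.0, n_points=128, n_rings=81))
        assert mesh.volume == pytest.approx(np.pi * 1.5 ** 2 * 20, rel=1e-2)

    def test_volume_converges_with_refinement(self):
        exact = np.pi * 1.5 ** 2 * 20
        errs = [abs(ff.ray_cast_surface(
            cylinder_rings(radius=1.5, length=20.0, n_points=n,
                           n_rings=41)).volume - exact)
                for n in (16, 32, 64, 128)]
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))

    def test_mismatched_ring_sizes_rejected(self):
        rings = cylinder_rings(n_points=64, n_rings=3)
        with pytest.raises(ValidationError):
            ff.ray_cast_surface(rings, n_points=32)

    def test_twist_detected_without_alignment(self):
        rings = cylinder_rings(n_points=64, n_rings=3).copy()
        rings[1] = np.roll(rings[1], 32, axis=0)  # 180 degree start mismatch
        with pytest.raises(ValidationError, match="self-intersecting"):
            ff.ray_cast_surface(rings, align_rings=False)

    def test_alignment_recovers_twisted_input(self):
        rings = cylinder_rings(n_points=64, n_rings=3).copy()
        rings[1] = np.roll(rings[1], 32, axis=0)
        mesh = ff.ray_cast_surface(rings, align_rings=True)
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(np.pi * 1.5 ** 2 * 10, rel=2e-2)


class TestReconstructStack:
    def test_oct_without_centerline_reconstructed_straight(self, paired_stacks):
        _, _, oct_stack = paired_stacks
        rings, mesh = ff.reconstruct_stack(oct_stack)
        assert mesh.is_watertight
        centroids = rings.mean(axis=1)
        assert np.abs(centroids[:, :2]).max() < 1e-6
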