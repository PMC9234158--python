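"""CTA-OCT lumen fusion.

OCT supplies accurate lumen contours but no 3D curvature; CTA supplies the
curved centerline but coarse lumen sizing.  Fusion registers the OCT pullback
to the CTA stack using bifurcation (side-branch) directions as the shared
landmarks -- a longitudinal offset plus a circumferential rotation, with a
piecewise-linear twist between multiple landmarks -- interpolates the OCT
contours onto the CTA frame spacing, exchanges the CTA lumens for the
registered OCT lumens inside pullback coverage, and scales the uncovered CTA
contours so the area profile stays continuous across the junctions.

OCT contours are exchanged at native size: OCT is treated as the lumen
ground truth and is never rescaled to CTA dimensions.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .contours import (Contour, ContourStack, Modality, SurfaceMesh,
                       ValidationError)
from .reconstruct import (DEFAULT_N_POINTS, estimate_mother_vessel,
                          place_contours, ray_cast_surface,
                          straight_centerline)

log = logging.getLogger(__name__)

DEFAULT_TAPER_MM = 5.0


class FusionError(ValidationError):
    pass


def _wrap_deg(a):
    """Wrap angle difference to (-180, 180]."""
    return -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


@dataclass
class RegistrationResult:
    """Rigid longitudinal offset + per-landmark circumferential rotation.

    ``rotation_at(z)`` interpolates the rotation linearly in z between
    matched landmarks (a twist model for catheter drift along the pullback)
    and extrapolates the nearest landmark's rotation beyond them.
    """

    longitudinal_offset_mm: float
    rotation_knots_z_mm: np.ndarray    # CTA-frame z of each matched landmark
    rotation_knots_deg: np.ndarray
    matched_pairs: list
    unmatched_cta: list = field(default_factory=list)
    unmatched_oct: list = field(default_factory=list)
    residual_deg: float = 0.0   # direction mismatch after fit (0: the
    # per-landmark rotation passes through every matched direction)
    residual_z_mm: float = 0.0  # longitudinal misfit after the global offset

    def rotation_at(self, z_mm):
        z = np.asarray(z_mm, dtype=float)
        k, r = self.rotation_knots_z_mm, self.rotation_knots_deg
        if len(k) == 1:
            return np.full_like(z, r[0], dtype=float) if z.ndim else float(r[0])
        # interpolate on the unwrapped rotation sequence
        r_unwrapped = np.concatenate(
            [[r[0]], r[0] + np.cumsum(_wrap_deg(np.diff(r)))])
        out = np.interp(z, k, r_unwrapped)
        return float(out) if np.ndim(z_mm) == 0 else out

    def to_dict(self) -> dict:
        return {
            "longitudinal_offset_mm": self.longitudinal_offset_mm,
            "rotation_knots_z_mm": np.asarray(self.rotation_knots_z_mm).tolist(),
            "rotation_knots_deg": np.asarray(self.rotation_knots_deg).tolist(),
            "n_matched_pairs": len(self.matched_pairs),
            "n_unmatched_cta": len(self.unmatched_cta),
            "n_unmatched_oct": len(self.unmatched_oct),
            "residual_deg": self.residual_deg,
            "residual_z_mm": self.residual_z_mm,
        }


@dataclass
class FusionModel:
    """Merged contour stack on the CTA centerline plus its surface mesh."""

    stack: ContourStack
    mesh: SurfaceMesh
    registration: RegistrationResult
    coverage: np.ndarray       # bool per fused frame: True inside OCT coverage
    rings: np.ndarray


# ---------------------------------------------------------------------------
# landmark matching and registration
# ---------------------------------------------------------------------------

def match_bifurcations(cta: ContourStack, oct_stack: ContourStack):
    """Order-preserving landmark matching minimizing sum |dz| after a global
    longitudinal offset.

    Returns (matched pairs, unmatched CTA markers, unmatched OCT markers);
    pair count is min(#CTA, #OCT) landmarks.
    """
    mc = sorted(cta.bifurcations, key=lambda m: m.z_mm)
    mo = sorted(oct_stack.bifurcations, key=lambda m: m.z_mm)
    if not mc or not mo:
        raise FusionError("both stacks need >= 1 bifurcation marker; "
                          "fusion is impossible without references")
    k = min(len(mc), len(mo))
    best = None
    for ic in itertools.combinations(range(len(mc)), k):
        for io in itertools.combinations(range(len(mo)), k):
            dz = np.array([mc[a].z_mm - mo[b].z_mm for a, b in zip(ic, io)])
            offset = dz.mean()
            cost = np.abs(dz - offset).sum()
            # ties (e.g. a single remaining landmark) are broken in favor of
            # the smaller global offset: pullback misalignment is small
            # compared with the spacing between side branches
            key = (round(cost, 9), abs(offset))
            if best is None or key < best[0]:
                best = (key, ic, io)
    _, ic, io = best
    pairs = [(mc[a], mo[b]) for a, b in zip(ic, io)]
    unmatched_cta = [mc[a] for a in range(len(mc)) if a not in ic]
    unmatched_oct = [mo[b] for b in range(len(mo)) if b not in io]
    if unmatched_cta or unmatched_oct:
        log.info("unmatched markers: %d CTA, %d OCT",
                 len(unmatched_cta), len(unmatched_oct))
    return pairs, unmatched_cta, unmatched_oct


def register(cta: ContourStack, oct_stack: ContourStack) -> RegistrationResult:
    """Least-squares longitudinal offset plus per-landmark circumferential
    rotation (CTA direction minus OCT direction, wrapped to (-180, 180])."""
    pairs, un_c, un_o = match_bifurcations(cta, oct_stack)
    dz = np.array([c.z_mm - o.z_mm for c, o in pairs])
    offset = float(dz.mean())
    rot = _wrap_deg(np.array([c.direction_deg - o.direction_deg
                              for c, o in pairs]))
    knots_z = np.array([c.z_mm for c, _ in pairs])
    order = np.argsort(knots_z)
    knots_z, rot = knots_z[order], rot[order]
    if len(rot) > 1 and np.any(np.abs(_wrap_deg(np.diff(rot))) > 90.0):
        warnings.warn("adjacent landmark rotations differ by > 90 deg; "
                      "possible marker mismatch, proceeding")
    return RegistrationResult(
        longitudinal_offset_mm=offset,
        rotation_knots_z_mm=knots_z,
        rotation_knots_deg=rot,
        matched_pairs=pairs,
        unmatched_cta=un_c,
        unmatched_oct=un_o,
        residual_deg=0.0,
        residual_z_mm=float(np.max(np.abs(dz - offset))),
    )


# ---------------------------------------------------------------------------
# contour interpolation and exchange
# ---------------------------------------------------------------------------

def _rotated_profile(contour: Contour, rotation_deg: float, n_theta: int):
    """Radius profile of the contour in the rotated (CTA) frame basis: a
    feature at OCT-local angle a appears at a + rotation."""
    _, r = contour.radius_profile(n_theta)
    if rotation_deg == 0.0:
        return r
    theta = np.arange(n_theta) * (360.0 / n_theta)
    # r_cta(theta) = r_local(theta - rotation)
    return np.interp((theta - rotation_deg) % 360.0, theta, r, period=360.0)


def interpolate_oct_to_cta_spacing(oct_stack: ContourStack,
                                   target_spacing: float,
                                   registration: RegistrationResult | None = None,
                                   target_z_mm: np.ndarray | None = None,
                                   n_theta: int | None = None) -> ContourStack:
    """Resample the OCT stack onto the CTA frame interval.

    At each target z the radius function r(theta) is linearly interpolated
    between the flanking OCT frames (after applying the registration
    rotation); target positions outside the OCT extent are excluded and the
    resulting coverage is logged.  ``target_z_mm`` positions are expressed in
    OCT-local z; by default the grid is multiples of ``target_spacing``.
    """
    if target_spacing <= 0:
        raise FusionError("target spacing must be > 0")
    if n_theta is None:
        n_theta = len(oct_stack.contours[0].points)
    z_oct = oct_stack.z_mm
    if target_z_mm is None:
        target_z_mm = np.arange(0.0, oct_stack.extent_mm + 1e-9, target_spacing)
    kept = [z for z in target_z_mm
            if z_oct[0] - 1e-9 <= z <= z_oct[-1] + 1e-9]
    if len(kept) < len(target_z_mm):
        log.info("OCT covers %d of %d target frames", len(kept),
                 len(target_z_mm))
    contours = []
    for k, z in enumerate(kept):
        zc = float(np.clip(z, z_oct[0], z_oct[-1]))
        j = min(int(np.floor(zc / oct_stack.spacing)), oct_stack.n_frames - 2)
        w = (zc - z_oct[j]) / oct_stack.spacing
        w = float(np.clip(w, 0.0, 1.0))
        if registration is not None:
            rot = registration.rotation_at(z + registration.longitudinal_offset_mm)
        else:
            rot = 0.0
        r_lo = _rotated_profile(oct_stack.contours[j], rot, n_theta)
        r_hi = _rotated_profile(oct_stack.contours[j + 1], rot, n_theta)
        r = (1.0 - w) * r_lo + w * r_hi
        contours.append(Contour.from_radius_profile(r, k))
    extent = (len(contours) - 1) * target_spacing
    kept_markers = [m for m in oct_stack.bifurcations
                    if m.z_mm <= extent + 1e-9]
    return ContourStack(modality=Modality.OCT, contours=contours,
                        spacing=target_spacing, bifurcations=kept_markers)


def fuse(cta: ContourStack, oct_stack: ContourStack,
         taper_mm: float = DEFAULT_TAPER_MM,
         n_points: int = DEFAULT_N_POINTS,
         remove_side_branches: bool = True) -> FusionModel:
    """Exchange CTA lumens for registered OCT lumens and mesh the result.

    Inside OCT coverage the fused contours are the registered, interpolated
    OCT lumens placed on the CTA centerline frames.  Outside coverage the
    CTA contours are scaled about their centroids by a factor tapering
    linearly from sqrt(A_OCT/A_CTA) at the junction to 1 over ``taper_mm``,
    automating the size adjustment of the remaining CTA lumens so the lumen
    area profile is continuous.
    """
    reg = register(cta, oct_stack)
    work_cta = estimate_mother_vessel(cta) if remove_side_branches else cta
    work_oct = (estimate_mother_vessel(oct_stack) if remove_side_branches
                else oct_stack)

    z_cta = cta.z_mm
    off = reg.longitudinal_offset_mm
    cover = (z_cta >= off - 1e-9) & (z_cta <= off + oct_stack.extent_mm + 1e-9)
    if cover.sum() < 2:
        raise FusionError("OCT pullback covers fewer than 2 CTA frames")

    target_local = z_cta[cover] - off
    oct_on_cta = interpolate_oct_to_cta_spacing(
        work_oct, cta.spacing, registration=reg, target_z_mm=target_local,
        n_theta=n_points)

    fused = []
    cov_idx = np.where(cover)[0]
    oct_areas = {ki: c.area for ki, c in zip(cov_idx, oct_on_cta.contours)}
    k_lo, k_hi = int(cov_idx[0]), int(cov_idx[-1])
    s_lo = np.sqrt(oct_areas[k_lo] / work_cta.contours[k_lo].area)
    s_hi = np.sqrt(oct_areas[k_hi] / work_cta.contours[k_hi].area)

    for k, c in enumerate(work_cta.contours):
        if cover[k]:
            oc = oct_on_cta.contours[list(cov_idx).index(k)]
            fused.append(Contour(oc.points.copy(), c.z_index))
        else:
            if k < k_lo:
                d = (k_lo - k) * cta.spacing
                s_b = s_lo
            else:
                d = (k - k_hi) * cta.spacing
                s_b = s_hi
            frac = max(0.0, 1.0 - d / taper_mm) if taper_mm > 0 else 0.0
            s = 1.0 + (s_b - 1.0) * frac
            if s == 1.0:
                fused.append(Contour(c.points.copy(), c.z_index))
            else:
                cen = c.centroid
                fused.append(Contour(cen + s * (c.points - cen), c.z_index))

    fused_stack = ContourStack(
        modality=Modality.FUSION, contours=fused, spacing=cta.spacing,
        centerline=cta.centerline, bifurcations=list(cta.bifurcations))

    centerline = cta.centerline
    if centerline is None:
        centerline = straight_centerline(fused_stack.extent_mm,
                                         n=fused_stack.n_frames)
    rings = place_contours(fused_stack, centerline, n_points=n_points)
    mesh = ray_cast_surface(rings, n_points=n_points)
    return FusionModel(stack=fused_stack, mesh=mesh, registration=reg,
                       coverage=cover, rings=rings)
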