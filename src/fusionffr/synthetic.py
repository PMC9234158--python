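"""Ground-truthed synthetic vessels, paired CTA/OCT stacks, and FFR cohorts.

Every other module is testable against these generators: a vessel is an
analytic radius field r(z, theta) on a parametric centerline (straight,
planar arc or helix) with an optional Gaussian stenosis of exact area
severity and compactly-supported side-branch ostium bulges.  Imaging
emulates the two modalities: CTA samples at 0.25 mm on the true centerline
with a multiplicative radial bias plus noise (its low resolution); OCT
samples at 0.2 mm in probe-local frames with an applied circumferential
rotation and longitudinal offset that fusion must recover, and small radial
noise.  Cohort generation draws wire-FFR values from a truncated normal
fitted to the clinical distribution (median 0.82, IQR 0.74-0.87) and adds
modality-specific Gaussian errors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .contours import (BifurcationMarker, Contour, ContourStack, Modality,
                       ValidationError)
from .reconstruct import build_local_frames

CTA_SPACING_MM = 0.25
OCT_SPACING_MM = 0.2
OCT_PULLBACK_MM_S = 20.0
OCT_FRAME_RATE_FPS = 100.0


@dataclass
class VesselSpec:
    centerline_kind: str = "straight"        # straight | planar_arc | helix
    length_mm: float = 20.0
    base_radius_mm: float = 1.5
    stenosis: tuple | None = None            # (center_z, severity_pct, length)
    bifurcations: list = field(default_factory=list)  # (z, dir_deg, diam)
    bend_angle_deg: float = 90.0             # planar_arc total bend
    helix_radius_mm: float = 2.0
    helix_pitch_mm: float = 10.0
    ostium_bump_mm: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.stenosis is not None:
            z0, sev, ln = self.stenosis
            if not (0 <= sev < 100):
                raise ValidationError("severity must be in [0, 100)")
            if not (0 <= z0 <= self.length_mm):
                raise ValidationError("stenosis center outside vessel")


@dataclass
class ImagingSpec:
    cta_spacing_mm: float = CTA_SPACING_MM
    oct_spacing_mm: float = OCT_SPACING_MM
    oct_rotation_deg: float = 0.0      # unknown to fusion, to be recovered
    oct_offset_mm: float = 0.0         # true z where the OCT pullback starts
    oct_coverage_mm: float | None = None  # pullback length (default: to end)
    cta_radial_bias: float = 1.0       # multiplicative (low CTA resolution)
    cta_radial_noise_sd: float = 0.0   # fraction of local radius
    oct_radial_noise_sd: float = 0.0   # fraction of local radius
    marker_direction_jitter_deg: float = 0.0
    marker_z_jitter_mm: float = 0.0
    n_contour_points: int = 96
    seed: int = 0

    def __post_init__(self):
        if self.cta_spacing_mm <= 0 or self.oct_spacing_mm <= 0:
            raise ValidationError("spacings must be > 0")
        if self.cta_radial_noise_sd < 0 or self.oct_radial_noise_sd < 0:
            raise ValidationError("noise SDs must be >= 0")


class VesselGeometry:
    """Analytic vessel: centerline position by arc length plus the radius
    field r(z, theta); ground-truth lumen areas in closed form."""

    def __init__(self, spec: VesselSpec):
        self.spec = spec

    # -- centerline ---------------------------------------------------------
    def centerline_point(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        k = self.spec.centerline_kind
        if k == "straight":
            p = np.stack([np.zeros_like(s), np.zeros_like(s), s], axis=1)
        elif k == "planar_arc":
            ang_total = np.radians(self.spec.bend_angle_deg)
            rc = self.spec.length_mm / ang_total
            a = s / rc
            p = np.stack([rc * (1 - np.cos(a)), np.zeros_like(s),
                          rc * np.sin(a)], axis=1)
        elif k == "helix":
            a = self.spec.helix_radius_mm
            b = self.spec.helix_pitch_mm / (2 * np.pi)
            c = np.sqrt(a * a + b * b)
            t = s / c
            p = np.stack([a * np.cos(t) - a, a * np.sin(t), b * t], axis=1)
        else:
            raise ValidationError(f"unknown centerline kind {k!r}")
        return p

    def sampled_centerline(self, ds: float = 0.1):
        s = np.arange(0.0, self.spec.length_mm + 1e-9, ds)
        return self.centerline_point(s)

    # -- radius field -------------------------------------------------------
    def radius(self, z, theta):
        z = np.asarray(z, dtype=float)
        theta = np.asarray(theta, dtype=float)
        r = np.full(np.broadcast(z, theta).shape, self.spec.base_radius_mm)
        if self.spec.stenosis is not None:
            z0, sev, ln = self.spec.stenosis
            sigma = ln / 4.0
            g = np.exp(-0.5 * ((z - z0) / sigma) ** 2)
            r = self.spec.base_radius_mm * np.sqrt(1.0 - (sev / 100.0) * g)
            r = np.broadcast_to(r, np.broadcast(z, theta).shape).copy()
        for (zb, dir_deg, diam) in self.spec.bifurcations:
            half_z = diam / 2.0
            half_th = np.radians(30.0)
            dz = np.abs(z - zb)
            wz = np.where(dz < half_z, np.cos(np.pi * dz / diam) ** 2, 0.0)
            dth = np.angle(np.exp(1j * (theta - np.radians(dir_deg))))
            wt = np.where(np.abs(dth) < half_th,
                          np.cos(dth / half_th * np.pi / 2) ** 2, 0.0)
            r = r + self.spec.ostium_bump_mm * wz * wt
        return r

    def area(self, z) -> float:
        """Exact lumen area away from ostia (the stenosis is axisymmetric)."""
        r = self.radius(np.asarray(z, dtype=float), 0.0)
        return np.pi * r ** 2

    @property
    def mla_mm2(self) -> float:
        if self.spec.stenosis is None:
            return float(np.pi * self.spec.base_radius_mm ** 2)
        _, sev, _ = self.spec.stenosis
        return float((1.0 - sev / 100.0) * np.pi
                     * self.spec.base_radius_mm ** 2)

    @property
    def area_stenosis_pct(self) -> float:
        if self.spec.stenosis is None:
            return 0.0
        return float(self.spec.stenosis[1])


def generate_vessel(spec: VesselSpec) -> VesselGeometry:
    """Deterministic ground-truth geometry for the given specification."""
    return VesselGeometry(spec)


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

def _noisy_profile(r, noise_sd, rng):
    """Multiplicative radial noise, circularly smoothed so the polygon stays
    simple."""
    if noise_sd == 0.0:
        return r
    n = len(r)
    eps = rng.normal(0.0, noise_sd, n)
    kernel = np.array([0.25, 0.5, 0.25])
    eps = np.convolve(np.concatenate([eps[-1:], eps, eps[:1]]), kernel,
                      mode="valid")
    return r * (1.0 + eps)


def image_vessel(geom: VesselGeometry, imaging: ImagingSpec):
    """Sample the vessel as a (CTA stack, OCT stack) pair.

    CTA frames lie on the true centerline at the CTA interval with radial
    bias/noise applied.  OCT frames are probe-local (no centerline) at the
    OCT interval, rotated by ``oct_rotation_deg`` and starting at true z =
    ``oct_offset_mm``; bifurcation markers are emitted in both stacks with
    directions consistent with the applied rotation.
    """
    rng = np.random.default_rng(imaging.seed)
    npts = imaging.n_contour_points
    theta = np.arange(npts) * (2 * np.pi / npts)
    length = geom.spec.length_mm

    # CTA ------------------------------------------------------------------
    z_cta = np.arange(0.0, length + 1e-9, imaging.cta_spacing_mm)
    cta_contours = []
    for k, z in enumerate(z_cta):
        r = geom.radius(z, theta) * imaging.cta_radial_bias
        r = _noisy_profile(r, imaging.cta_radial_noise_sd, rng)
        cta_contours.append(Contour.from_radius_profile(r, k))
    centerline = build_local_frames(geom.centerline_point(z_cta))
    cta_markers = [
        BifurcationMarker(
            z_mm=float(np.clip(zb + rng.normal(0, imaging.marker_z_jitter_mm)
                               if imaging.marker_z_jitter_mm else zb,
                               0, length)),
            direction_deg=float(
                (db + (rng.normal(0, imaging.marker_direction_jitter_deg)
                       if imaging.marker_direction_jitter_deg else 0.0))
                % 360.0),
            branch_diameter_mm=diam)
        for (zb, db, diam) in geom.spec.bifurcations]
    cta = ContourStack(modality=Modality.CTA, contours=cta_contours,
                       spacing=imaging.cta_spacing_mm, centerline=centerline,
                       bifurcations=cta_markers)

    # OCT ------------------------------------------------------------------
    z0 = imaging.oct_offset_mm
    z1 = length if imaging.oct_coverage_mm is None else min(
        length, z0 + imaging.oct_coverage_mm)
    z_true = np.arange(z0, z1 + 1e-9, imaging.oct_spacing_mm)
    rot = np.radians(imaging.oct_rotation_deg)
    oct_contours = []
    for j, z in enumerate(z_true):
        # a feature at true angle phi appears at local angle phi - rotation
        r = geom.radius(z, theta + rot)
        r = _noisy_profile(r, imaging.oct_radial_noise_sd, rng)
        oct_contours.append(Contour.from_radius_profile(r, j))
    oct_markers = [
        BifurcationMarker(
            z_mm=float(np.clip(
                zb - z0 + (rng.normal(0, imaging.marker_z_jitter_mm)
                           if imaging.marker_z_jitter_mm else 0.0),
                0, z_true[-1] - z_true[0])),
            direction_deg=float(
                (db - imaging.oct_rotation_deg
                 + (rng.normal(0, imaging.marker_direction_jitter_deg)
                    if imaging.marker_direction_jitter_deg else 0.0))
                % 360.0),
            branch_diameter_mm=diam)
        for (zb, db, diam) in geom.spec.bifurcations
        if z0 <= zb <= z1]
    oct_stack = ContourStack(
        modality=Modality.OCT, contours=oct_contours,
        spacing=imaging.oct_spacing_mm,
        pullback_speed=OCT_PULLBACK_MM_S, frame_rate=OCT_FRAME_RATE_FPS,
        bifurcations=oct_markers)
    return cta, oct_stack


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

FFR_MEDIAN = 0.82
FFR_IQR = (0.74, 0.87)
FFR_RANGE = (0.40, 1.00)
DEFAULT_ERROR_SD = {"fusion_ffr": 0.06, "ct_ffr": 0.08, "oct_ffr": 0.07}
DEFAULT_BIAS = {"fusion_ffr": 0.0, "ct_ffr": -0.02, "oct_ffr": 0.0}


def _truncnorm(mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def generate_cohort(n: int, prevalence: float | None = None,
                    error_sd: dict | None = None, bias: dict | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Per-patient (wire FFR, computational FFR) table.

    Wire FFR follows a truncated normal fitted to the clinical summary
    (median 0.82, IQR 0.74-0.87); when ``prevalence`` is given the location
    is shifted so P(FFR <= 0.80) equals it.  Computational FFRs add Gaussian
    errors with the configured SDs (defaults 0.06 / 0.08 / 0.07 for fusion /
    CTA / OCT, matching the agreement scale of the three modalities).
    """
    if n < 10:
        raise ValidationError("cohort size must be >= 10")
    rng = np.random.default_rng(seed)
    sd = (FFR_IQR[1] - FFR_IQR[0]) / (2 * stats.norm.ppf(0.75))
    mean = FFR_MEDIAN
    if prevalence is not None:
        def excess(m):
            return _truncnorm(m, sd, *FFR_RANGE).cdf(0.80) - prevalence
        mean = optimize.brentq(excess, 0.5, 1.1)
    dist = _truncnorm(mean, sd, *FFR_RANGE)
    ffr = dist.ppf(rng.uniform(size=n))
    err = {**DEFAULT_ERROR_SD, **(error_sd or {})}
    off = {**DEFAULT_BIAS, **(bias or {})}
    data = {"patient_id": np.arange(1, n + 1), "ffr": ffr}
    for col in ("fusion_ffr", "ct_ffr", "oct_ffr"):
        noise = rng.normal(0.0, err[col], n) if err[col] > 0 else 0.0
        data[col] = np.clip(ffr + off[col] + noise, 0.2, 1.05)
    return pd.DataFrame(data)
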