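import numpy as np
import pytest

from fusionffr import (Contour, ray_cast_surface, VesselSpec, ImagingSpec,
                       generate_vessel, image_vessel)


def circle_points(r=1.5, n=360, center=(0.0, 0.0)):
    th = np.arange(n) * 2 * np.pi / n
    return np.stack([center[0] + r * np.cos(th),
                     center[1] + r * np.sin(th)], axis=1)


def cylinder_rings(radius=1.5, length=10.0, n_points=96, n_rings=41):
    th = np.arange(n_points) * 2 * np.pi / n_points
    return np.stack([
        np.stack([radius * np.cos(th), radius * np.sin(th),
                  np.full(n_points, z)], axis=1)
        for z in np.linspace(0.0, length, n_rings)])


def stenosed_rings(severity_pct, radius=1.5, length=12.0, center_z=6.0,
                   stenosis_len=5.0, n_points=96, dz=0.15):
    th = np.arange(n_points) * 2 * np.pi / n_points
    sigma = stenosis_len / 4.0
    rings = []
    for z in np.arange(0.0, length + 1e-9, dz):
        r = radius * np.sqrt(
            1 - severity_pct / 100.0 * np.exp(-0.5 * ((z - center_z) / sigma) ** 2))
        rings.append(np.stack([r * np.cos(th), r * np.sin(th),
                               np.full(n_points, z)], axis=1))
    return np.stack(rings)


@pytest.fixture
def circle_contour():
    return Contour(circle_points(), 0)


@pytest.fixture
def cylinder_mesh():
    return ray_cast_surface(cylinder_rings())


@pytest.fixture
def paired_stacks():
    """CTA (biased 20% in radius) + OCT stacks of a stenosed vessel with two
    side branches, OCT rotated 30 deg and shifted 2 mm."""
    geom = generate_vessel(VesselSpec(
        length_mm=20.0, base_radius_mm=1.5, stenosis=(10.0, 60.0, 6.0),
        bifurcations=[(4.0, 90.0, 1.0), (16.0, 200.0, 1.0)]))
    cta, oct_stack = image_vessel(geom, ImagingSpec(
        oct_rotation_deg=30.0, oct_offset_mm=2.0, cta_radial_bias=1.2))
    return geom, cta, oct_stack
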