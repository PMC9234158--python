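"""Lumen contour data model and file I/O.

All coordinates are millimetres.  A :class:`ContourStack` holds the ordered
cross-sectional lumen contours of one imaging modality (CTA at 0.25 mm frame
spacing along a 3D centerline, OCT at 0.2 mm spacing in probe-local
coordinates), together with side-branch (bifurcation) markers that serve as
registration landmarks.  Stacks are serialized to a small JSON dialect so
fixtures diff cleanly; see :func:`read_contour_stack` for the schema.
"""
from __future__ import annotations

import json
import logging
import struct
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

log = logging.getLogger(__name__)

MM = "mm"  # the only accepted unit in contour files


class Modality(str, Enum):
    CTA = "CTA"
    OCT = "OCT"
    FUSION = "FUSION"


class ContourError(ValueError):
    """Base class for contour model errors."""


class ValidationError(ContourError):
    """An invariant of the contour data model is violated."""


class ParseError(ContourError):
    """A contour file is malformed."""


# ---------------------------------------------------------------------------
# polygon geometry
# ---------------------------------------------------------------------------

def signed_polygon_area(points: np.ndarray) -> float:
    """Shoelace area; positive for counter-clockwise vertex order."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def is_simple_polygon(points: np.ndarray) -> bool:
    p = np.asarray(points, dtype=float)
    if len(p) < 3:
        return False
    try:
        return bool(_ShapelyPolygon(p).is_valid)
    except Exception:
        return False


def polygon_area(points: np.ndarray) -> float:
    """Area (mm^2) of a simple closed polygon given as an ordered vertex list.

    Raises :class:`ValidationError` for self-intersecting input.  Orientation
    is not required: clockwise input yields the same positive area.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
        raise ValidationError("polygon needs >= 3 two-dimensional points")
    if not is_simple_polygon(p):
        raise ValidationError("polygon is self-intersecting")
    return abs(signed_polygon_area(p))


def polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-300:
        return p.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Contour:
    """One planar lumen contour (mm) at integer frame index ``z_index``.

    Vertices are stored counter-clockwise as seen from the distal direction;
    clockwise input is auto-reversed with a logged warning (vendor exports
    differ in orientation convention).  ``area`` and ``centroid`` are always
    derived from the vertices, never trusted from a file.
    """

    points: np.ndarray
    z_index: int

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValidationError(
                f"contour {self.z_index}: points must be an (N, 2) array")
        if len(p) < 8:
            raise ValidationError(
                f"contour {self.z_index}: needs >= 8 points, got {len(p)}")
        if not is_simple_polygon(p):
            raise ValidationError(
                f"contour {self.z_index}: polygon is self-intersecting")
        sa = signed_polygon_area(p)
        if sa == 0.0:
            raise ValidationError(f"contour {self.z_index}: zero area")
        if sa < 0:
            log.warning("contour %d: clockwise vertex order, auto-reversing",
                        self.z_index)
            p = p[::-1].copy()
        self.points = p

    @property
    def area(self) -> float:
        return signed_polygon_area(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.points)

    def radius_profile(self, n_theta: int, center: np.ndarray | None = None):
        """Radius r(theta) sampled at ``n_theta`` uniform angles about
        ``center`` (default: the area centroid).

        The contour is treated as star-shaped about the center, which holds
        for coronary lumens; radii are interpolated in polar coordinates
        with period 2*pi, so a contour whose vertices already sit at the
        uniform angles is reproduced exactly.
        """
        c = self.centroid if center is None else np.asarray(center, float)
        d = self.points - c
        ang = np.arctan2(d[:, 1], d[:, 0]) % (2 * np.pi)
        rad = np.hypot(d[:, 0], d[:, 1])
        order = np.argsort(ang, kind="stable")
        ang, rad = ang[order], rad[order]
        theta = np.arange(n_theta) * (2 * np.pi / n_theta)
        r = np.interp(theta, ang, rad, period=2 * np.pi)
        return theta, r

    @classmethod
    def from_radius_profile(cls, r: np.ndarray, z_index: int,
                            center=(0.0, 0.0)) -> "Contour":
        r = np.asarray(r, dtype=float)
        theta = np.arange(len(r)) * (2 * np.pi / len(r))
        pts = np.stack([center[0] + r * np.cos(theta),
                        center[1] + r * np.sin(theta)], axis=1)
        return cls(points=pts, z_index=z_index)


@dataclass
class Centerline:
    """Ordered 3D centerline with per-point orthonormal frames.

    ``frames[i]`` rows are (tangent, normal, binormal); frames are built with
    the rotation-minimizing double-reflection transport (see the
    reconstruction module) so the circumferential origin does not spin along
    curved vessels.
    """

    points: np.ndarray
    frames: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        f = np.asarray(self.frames, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or len(p) < 2:
            raise ValidationError("centerline needs >= 2 3D points")
        if np.any(np.linalg.norm(np.diff(p, axis=0), axis=1) == 0.0):
            raise ValidationError("centerline has duplicate consecutive points")
        if f.shape != (len(p), 3, 3):
            raise ValidationError("frames must be (N, 3, 3)")
        eye = np.eye(3)
        if np.max(np.abs(f @ np.transpose(f, (0, 2, 1)) - eye)) > 1e-9:
            raise ValidationError("frames are not orthonormal to 1e-9")
        self.points, self.frames = p, f

    @property
    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])


@dataclass
class BifurcationMarker:
    """Side-branch ostium landmark: longitudinal position (mm from stack
    origin), circumferential angle of the ostium in the (normal, binormal)
    frame basis (degrees in [0, 360)), and side-branch diameter (mm)."""

    z_mm: float
    direction_deg: float
    branch_diameter_mm: float

    def __post_init__(self):
        if not (0.0 <= self.direction_deg < 360.0):
            raise ValidationError(
                f"bifurcation direction {self.direction_deg} not in [0, 360)")
        if self.branch_diameter_mm <= 0:
            raise ValidationError("branch diameter must be positive")


@dataclass
class ContourStack:
    """Ordered proximal-to-distal lumen contours of one modality."""

    modality: Modality
    contours: list
    spacing: float
    centerline: Centerline | None = None
    pullback_speed: float | None = None
    frame_rate: float | None = None
    bifurcations: list = field(default_factory=list)

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValidationError("spacing must be > 0")
        idx = [c.z_index for c in self.contours]
        if idx != list(range(idx[0] if idx else 0, (idx[0] if idx else 0) + len(idx))):
            raise ValidationError("contours must be sorted by z_index without gaps")
        if self.pullback_speed is not None and self.frame_rate is not None:
            implied = self.pullback_speed / self.frame_rate
            if abs(implied - self.spacing) > 1e-9:
                raise ValidationError(
                    f"spacing {self.spacing} != pullback_speed/frame_rate "
                    f"= {implied}")
        ext = self.extent_mm
        for m in self.bifurcations:
            if not (-1e-9 <= m.z_mm <= ext + 1e-9):
                raise ValidationError(
                    f"bifurcation at z={m.z_mm} mm outside stack extent {ext} mm")

    @property
    def n_frames(self) -> int:
        return len(self.contours)

    @property
    def extent_mm(self) -> float:
        return (len(self.contours) - 1) * self.spacing if self.contours else 0.0

    @property
    def z_mm(self) -> np.ndarray:
        """Longitudinal position of each frame, measured from the stack origin."""
        return np.arange(len(self.contours)) * self.spacing

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.contours])

    def minimal_lumen_area(self) -> float:
        return float(self.areas.min())

    def copy(self) -> "ContourStack":
        return replace(
            self,
            contours=[Contour(c.points.copy(), c.z_index) for c in self.contours],
            bifurcations=list(self.bifurcations),
        )


@dataclass
class SurfaceMesh:
    """Triangulated lumen surface with per-triangle cap labels.

    Labels: 0 = wall, 1 = inlet cap, 2 = outlet cap.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    cap_labels: np.ndarray

    LABEL_WALL, LABEL_INLET, LABEL_OUTLET = 0, 1, 2

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.cap_labels = np.asarray(self.cap_labels, dtype=np.uint8)
        if self.cap_labels.shape[0] != self.triangles.shape[0]:
            raise ValidationError("one cap label per triangle required")

    def boundary_edges(self) -> list:
        """Edges not shared by exactly two triangles (empty iff watertight)."""
        e = np.vstack([self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
                       self.triangles[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return [tuple(edge) for edge in uniq[counts != 2]]

    @property
    def is_watertight(self) -> bool:
        return not self.boundary_edges()

    @property
    def euler_characteristic(self) -> int:
        v = len(self.vertices)
        f = len(self.triangles)
        e = len(np.unique(np.sort(np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
             self.triangles[:, [2, 0]]]), axis=1), axis=0))
        return v - e + f

    @property
    def volume(self) -> float:
        """Enclosed volume (mm^3); positive for outward-oriented normals."""
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def triangle_normals(self) -> np.ndarray:
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        n = np.cross(b - a, c - a)
        ln = np.linalg.norm(n, axis=1, keepdims=True)
        ln[ln == 0] = 1.0
        return n / ln

    def cap_plane(self, label: int):
        """(point, outward unit normal, radius) of the requested cap."""
        sel = self.cap_labels == label
        if not sel.any():
            raise ValidationError(f"mesh has no triangles with label {label}")
        tri = self.triangles[sel]
        verts = self.vertices[np.unique(tri)]
        center = verts.mean(axis=0)
        normal = self.triangle_normals()[sel].mean(axis=0)
        normal /= np.linalg.norm(normal)
        radius = float(np.linalg.norm(verts - center, axis=1).max())
        return center, normal, radius


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _stack_to_dict(stack: ContourStack) -> dict:
    d = {
        "units": MM,
        "modality": stack.modality.value,
        "spacing_mm": stack.spacing,
        "contours": [{"z_index": c.z_index, "points": c.points.tolist()}
                     for c in stack.contours],
        "bifurcations": [{"z_mm": m.z_mm, "direction_deg": m.direction_deg,
                          "branch_diameter_mm": m.branch_diameter_mm}
                         for m in stack.bifurcations],
    }
    if stack.pullback_speed is not None:
        d["pullback_speed_mm_s"] = stack.pullback_speed
    if stack.frame_rate is not None:
        d["frame_rate_fps"] = stack.frame_rate
    if stack.centerline is not None:
        d["centerline"] = stack.centerline.points.tolist()
    return d


def write_contour_stack(stack: ContourStack, path) -> None:
    Path(path).write_text(json.dumps(_stack_to_dict(stack), indent=1))


def read_contour_stack(path, fmt: str = "json") -> ContourStack:
    """Read a contour stack from the documented JSON dialect.

    Schema: ``{units: "mm", modality, spacing_mm, pullback_speed_mm_s?,
    frame_rate_fps?, centerline?: [[x,y,z]...], contours: [{z_index,
    points: [[x,y]...]}...], bifurcations: [{z_mm, direction_deg,
    branch_diameter_mm}...]}``.
    """
    if fmt != "json":
        raise ParseError(f"unsupported format {fmt!r}; only 'json' is defined")
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}, "
                         f"column {exc.colno}: {exc.msg}") from exc
    for key in ("modality", "spacing_mm", "contours"):
        if key not in raw:
            raise ParseError(f"{path}: missing required field {key!r}")
    if raw.get("units", MM) != MM:
        raise ParseError(f"{path}: unsupported units {raw.get('units')!r}; "
                         "only 'mm' is accepted")
    try:
        modality = Modality(raw["modality"])
    except ValueError:
        raise ParseError(f"{path}: unknown modality {raw['modality']!r}")
    contours = []
    for i, c in enumerate(raw["contours"]):
        if "z_index" not in c or "points" not in c:
            raise ParseError(f"{path}: contour {i} missing z_index/points")
        contours.append(Contour(np.asarray(c["points"], float), int(c["z_index"])))
    centerline = None
    if raw.get("centerline"):
        from .reconstruct import build_local_frames
        centerline = build_local_frames(np.asarray(raw["centerline"], float))
    bifurcations = [BifurcationMarker(m["z_mm"], m["direction_deg"],
                                      m["branch_diameter_mm"])
                    for m in raw.get("bifurcations", [])]
    return ContourStack(
        modality=modality,
        contours=contours,
        spacing=float(raw["spacing_mm"]),
        centerline=centerline,
        pullback_speed=raw.get("pullback_speed_mm_s"),
        frame_rate=raw.get("frame_rate_fps"),
        bifurcations=bifurcations,
    )


def write_mesh(mesh: SurfaceMesh, path, fmt: str = "ply") -> None:
    """Write a watertight mesh as binary STL or ascii PLY.

    Output is byte-stable for identical input.  PLY carries the per-face cap
    label as a uchar property; STL cannot, so labels are dropped with a
    warning.
    """
    be = mesh.boundary_edges()
    if be:
        raise ValidationError(
            f"mesh is not watertight; {len(be)} boundary edges: {be[:10]}")
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "stl":
        warnings.warn("STL cannot carry cap labels; labels dropped")
        normals = mesh.triangle_normals().astype("<f4")
        v = mesh.vertices.astype("<f4")
        with open(path, "wb") as fh:
            fh.write(b"fusionffr binary STL".ljust(80, b"\0"))
            fh.write(struct.pack("<I", len(mesh.triangles)))
            for i, t in enumerate(mesh.triangles):
                fh.write(normals[i].tobytes())
                fh.write(v[t[0]].tobytes())
                fh.write(v[t[1]].tobytes())
                fh.write(v[t[2]].tobytes())
                fh.write(struct.pack("<H", 0))
    elif fmt == "ply":
        lines = [
            "ply", "format ascii 1.0", "comment fusionffr lumen surface",
            f"element vertex {len(mesh.vertices)}",
            "property double x", "property double y", "property double z",
            f"element face {len(mesh.triangles)}",
            "property list uchar int vertex_indices",
            "property uchar label",
            "end_header",
        ]
        for p in mesh.vertices:
            lines.append(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}")
        for t, lab in zip(mesh.triangles, mesh.cap_labels):
            lines.append(f"3 {t[0]} {t[1]} {t[2]} {int(lab)}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unsupported mesh format {fmt!r}")


def read_mesh(path) -> SurfaceMesh:
    """Read the ascii PLY dialect written by :func:`write_mesh`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "ply":
        raise ParseError(f"{path}: not a PLY file")
    nv = nf = None
    header_end = 0
    for i, ln in enumerate(lines):
        if ln.startswith("element vertex"):
            nv = int(ln.split()[-1])
        elif ln.startswith("element face"):
            nf = int(ln.split()[-1])
        elif ln == "end_header":
            header_end = i + 1
            break
    if nv is None or nf is None:
        raise ParseError(f"{path}: missing element declarations")
    verts = np.array([[float(x) for x in ln.split()]
                      for ln in lines[header_end:header_end + nv]])
    tris, labels = [], []
    for ln in lines[header_end + nv:header_end + nv + nf]:
        parts = ln.split()
        tris.append([int(parts[1]), int(parts[2]), int(parts[3])])
        labels.append(int(parts[4]))
    return SurfaceMesh(verts, np.array(tris), np.array(labels))
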