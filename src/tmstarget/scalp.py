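"""Continuous proportional coordinates (CPC) on the scalp and coil frames.

A coil placement is described by a scalp position ``s = (p_nz, p_al)`` and an
orientation ``theta``. ``p_nz`` is the proportional arc-length position along
the nasion (NZ) -> inion (IZ) direction, ``p_al`` along the left (AL) -> right
(AR) preauricular direction; both live in [0, 1].

Construction (plane slicing):

* sagittal curve = scalp surface ∩ plane(NZ, IZ, midpoint(AL, AR)), ordered
  from NZ to IZ over the top of the head;
* for a given ``p_nz``, the coronal curve = surface ∩ plane(AL, AR, q) where
  ``q`` is the sagittal point at arc fraction ``p_nz``, ordered from AL to AR
  through ``q``;
* ``(p_nz, p_al)`` maps to the point at arc fraction ``p_al`` along that
  coronal curve.

Curves are exact triangle-plane section chains (not vertex shortest paths),
which avoids staircase bias and converges with mesh refinement.

The coil's 0-degree direction at ``s`` lies in the tangent plane,
perpendicular to the intersection of the tangent plane with the plane through
``s``, AL and AR, and points backward (toward IZ). ``theta`` rotates the
handle about the outward normal; anticlockwise rotation viewed from outside
the head is positive, clockwise is negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import (
    DataError,
    DegenerateCoordinateError,
    FrameUndefinedError,
    NotReachableError,
)

__all__ = [
    "CPCCoordinate",
    "CoilFrame",
    "ScalpMesh",
    "sagittal_curve",
    "cpc_forward",
    "cpc_inverse",
    "coil_frame",
    "restore_placement_from_cortical_target",
]

LANDMARK_NAMES = ("NZ", "IZ", "AL", "AR")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise FrameUndefinedError("cannot normalize a (near-)zero vector")
    return v / n


@dataclass(frozen=True)
class CPCCoordinate:
    """Scalp position in continuous proportional coordinates."""

    p_nz: float
    p_al: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_nz <= 1.0 and 0.0 <= self.p_al <= 1.0):
            raise DataError(f"CPC coordinates must lie in [0,1]^2, got {self}")


@dataclass(frozen=True)
class CoilFrame:
    """Coil pose: center on the scalp, outward normal, 0-deg and handle directions."""

    center: np.ndarray
    normal: np.ndarray
    zero_dir: np.ndarray
    handle_dir: np.ndarray

    def __post_init__(self) -> None:
        for name in ("normal", "zero_dir", "handle_dir"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise DataError(f"{name} is not unit length")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if abs(self.normal @ self.zero_dir) > 1e-9:
            raise DataError("zero_dir is not perpendicular to normal")
        if abs(self.normal @ self.handle_dir) > 1e-9:
            raise DataError("handle_dir is not perpendicular to normal")


class ScalpMesh:
    """Triangulated scalp surface with the four fiducial landmarks.

    Landmark points must lie on the surface within a few edge lengths; they
    anchor the CPC construction. The mesh is expected to be a single
    connected 2-manifold patch (closed analytic heads and open scalp caps
    both work).
    """

    def __init__(self, mesh: trimesh.Trimesh, landmarks: dict[str, np.ndarray]):
        missing = [k for k in LANDMARK_NAMES if k not in landmarks]
        if missing:
            raise DataError(f"missing landmarks: {missing}")
        self.mesh = mesh
        self.landmarks = {k: np.asarray(landmarks[k], dtype=float) for k in LANDMARK_NAMES}
        if len(mesh.faces) == 0:
            raise DataError("empty mesh")
        tol = 4.0 * self.mean_edge_length
        for name, p in self.landmarks.items():
            d, _ = self.vertex_tree.query(p)
            if d > tol:
                raise DataError(
                    f"landmark {name} is {d:.1f} mm from the surface (tol {tol:.1f})"
                )
        if np.linalg.norm(self.landmarks["NZ"] - self.landmarks["IZ"]) < tol:
            raise DataError("degenerate landmarks: NZ and IZ coincide")

    # ------------------------------------------------------------ properties
    @cached_property
    def mean_edge_length(self) -> float:
        return float(self.mesh.edges_unique_length.mean())

    @cached_property
    def vertex_tree(self) -> cKDTree:
        return cKDTree(self.mesh.vertices)

    @property
    def nz(self) -> np.ndarray:
        return self.landmarks["NZ"]

    @property
    def iz(self) -> np.ndarray:
        return self.landmarks["IZ"]

    @property
    def al(self) -> np.ndarray:
        return self.landmarks["AL"]

    @property
    def ar(self) -> np.ndarray:
        return self.landmarks["AR"]

    @cached_property
    def landmark_centroid(self) -> np.ndarray:
        return np.mean([self.landmarks[k] for k in LANDMARK_NAMES], axis=0)

    @cached_property
    def up(self) -> np.ndarray:
        """Unit vector toward the vertex (top of the head)."""
        return _unit(np.cross(self.iz - self.nz, self.ar - self.al))

    @cached_property
    def sagittal(self) -> np.ndarray:
        return sagittal_curve(self)

    # ------------------------------------------------------------------- I/O
    @classmethod
    def load(cls, mesh_path: str | Path, landmark_path: str | Path) -> "ScalpMesh":
        """Load mesh (PLY/STL/OFF...) and landmarks (JSON or TSV)."""
        mesh = trimesh.load(str(mesh_path), force="mesh")
        lm_path = Path(landmark_path)
        if lm_path.suffix.lower() == ".json":
            raw = json.loads(lm_path.read_text())
            landmarks = {k: np.asarray(v, float) for k, v in raw.items()}
        else:
            landmarks = {}
            for line in lm_path.read_text().splitlines():
                parts = line.strip().split("\t")
                if not parts or parts[0].lower() in ("label", ""):
                    continue
                landmarks[parts[0]] = np.array([float(x) for x in parts[1:4]])
        return cls(mesh, landmarks)

    def save(self, mesh_path: str | Path, landmark_path: str | Path) -> None:
        self.mesh.export(str(mesh_path))
        payload = {k: v.tolist() for k, v in self.landmarks.items()}
        Path(landmark_path).write_text(json.dumps(payload, indent=2))


# --------------------------------------------------------------- curve plumbing
def _section_curves(scalp: ScalpMesh, origin: np.ndarray, normal: np.ndarray) -> list[np.ndarray]:
    sec = scalp.mesh.section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        raise DataError("plane does not intersect the scalp surface")
    return [np.asarray(c, dtype=float) for c in sec.discrete]


def _is_closed(curve: np.ndarray) -> bool:
    return bool(np.allclose(curve[0], curve[-1], atol=1e-9))


def _nearest_index(curve: np.ndarray, point: np.ndarray) -> tuple[int, float]:
    d = np.linalg.norm(curve - point, axis=1)
    i = int(np.argmin(d))
    return i, float(d[i])


def _polyline_length(curve: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(curve, axis=0), axis=1).sum())


def _split_loop(curve: np.ndarray, a: np.ndarray, b: np.ndarray) -> list[np.ndarray]:
    """Split a closed loop at the vertices nearest to a and b; return both arcs a->b."""
    pts = curve[:-1] if _is_closed(curve) else curve
    ia, _ = _nearest_index(pts, a)
    ib, _ = _nearest_index(pts, b)
    if ia == ib:
        raise DataError("degenerate split: endpoints coincide on the section curve")
    n = len(pts)
    idx_fwd = [(ia + k) % n for k in range(0, (ib - ia) % n + 1)]
    idx_bwd = [(ia - k) % n for k in range(0, (ia - ib) % n + 1)]
    arcs = []
    for idx in (idx_fwd, idx_bwd):
        arc = pts[idx].copy()
        # snap endpoints to the exact anchor points (they lie on the cut plane)
        arc[0] = a
        arc[-1] = b
        arcs.append(arc)
    return arcs


def _open_arc(curve: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Extract the a->b sub-arc of an open section curve."""
    ia, _ = _nearest_index(curve, a)
    ib, _ = _nearest_index(curve, b)
    if ia == ib:
        raise DataError("degenerate arc: endpoints coincide on the section curve")
    step = 1 if ib > ia else -1
    arc = curve[ia : ib + step : step].copy()
    arc[0] = a
    arc[-1] = b
    return arc


def _curve_through(
    scalp: ScalpMesh,
    origin: np.ndarray,
    normal: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    prefer: np.ndarray | None = None,
) -> np.ndarray:
    """Ordered section arc from a to b.

    ``prefer``: a point the arc should pass near (used to pick the correct
    branch); if None, the branch whose centroid is highest along ``scalp.up``
    is taken (the arc over the top of the head).
    """
    tol = 4.0 * scalp.mean_edge_length
    best = None
    for curve in _section_curves(scalp, origin, normal):
        _, da = _nearest_index(curve, a)
        _, db = _nearest_index(curve, b)
        if da > tol or db > tol:
            continue
        arcs = _split_loop(curve, a, b) if _is_closed(curve) else [_open_arc(curve, a, b)]
        for arc in arcs:
            if prefer is not None:
                score = -_nearest_index(arc, prefer)[1]
            else:
                score = float(np.mean((arc - scalp.landmark_centroid) @ scalp.up))
            if best is None or score > best[0]:
                best = (score, arc)
    if best is None:
        raise DataError("landmarks are not connectable on the section curve")
    return best[1]


def _arc_fractions(curve: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total < 1e-12:
        raise DataError("zero-length curve")
    return cum / total


def _point_at_fraction(curve: np.ndarray, frac: float) -> np.ndarray:
    fr = _arc_fractions(curve)
    frac = float(np.clip(frac, 0.0, 1.0))
    i = int(np.searchsorted(fr, frac, side="right") - 1)
    i = min(i, len(curve) - 2)
    span = fr[i + 1] - fr[i]
    t = 0.0 if span < 1e-15 else (frac - fr[i]) / span
    return (1 - t) * curve[i] + t * curve[i + 1]


def _project_fraction(curve: np.ndarray, point: np.ndarray) -> tuple[float, float]:
    """Arc fraction of the closest point on the polyline, and its distance."""
    p0 = curve[:-1]
    d = curve[1:] - p0
    seg_len2 = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.einsum("ij,ij->i", point - p0, d) / np.maximum(seg_len2, 1e-30), 0, 1)
    proj = p0 + t[:, None] * d
    dist = np.linalg.norm(proj - point, axis=1)
    i = int(np.argmin(dist))
    fr = _arc_fractions(curve)
    frac = fr[i] + t[i] * (fr[i + 1] - fr[i])
    return float(frac), float(dist[i])


# ------------------------------------------------------------------ operations
def sagittal_curve(scalp: ScalpMesh) -> np.ndarray:
    """Ordered NZ->IZ polyline over the top of the head (mid-sagittal section)."""
    mid = 0.5 * (scalp.al + scalp.ar)
    axis = scalp.iz - scalp.nz
    n = np.cross(axis, mid - scalp.nz)
    if np.linalg.norm(n) < 1e-6 * np.linalg.norm(axis):
        # symmetric head: the midpoint sits on the NZ-IZ axis, so use the
        # plane through NZ and IZ perpendicular to the ear-to-ear axis
        ear = scalp.ar - scalp.al
        n = ear - (ear @ axis) / (axis @ axis) * axis
        if np.linalg.norm(n) < 1e-9:
            raise DataError("landmarks degenerate: no mid-sagittal plane")
    return _curve_through(scalp, scalp.nz, _unit(n), scalp.nz, scalp.iz)


def _coronal_curve(scalp: ScalpMesh, q: np.ndarray) -> np.ndarray:
    """Ordered AL->AR polyline through the sagittal point q."""
    n = np.cross(scalp.ar - scalp.al, q - scalp.al)
    if np.linalg.norm(n) < 1e-9 * np.linalg.norm(scalp.ar - scalp.al):
        raise DegenerateCoordinateError(
            "coronal plane undefined: sagittal point collinear with AL-AR"
        )
    return _curve_through(scalp, scalp.al, _unit(n), scalp.al, scalp.ar, prefer=q)


def cpc_forward(scalp: ScalpMesh, c: CPCCoordinate) -> np.ndarray:
    """Surface point (mm) at CPC position ``c``.

    ``p_nz`` in {0, 1} is a pole where the coronal curve collapses onto
    NZ/IZ; it is rejected rather than silently collapsed.
    """
    if c.p_nz <= 0.0 or c.p_nz >= 1.0:
        raise DegenerateCoordinateError(
            f"p_nz={c.p_nz} is a pole: the coronal curve collapses to NZ/IZ"
        )
    q = _point_at_fraction(scalp.sagittal, c.p_nz)
    coronal = _coronal_curve(scalp, q)
    return _point_at_fraction(coronal, c.p_al)


def cpc_inverse(
    scalp: ScalpMesh, point: np.ndarray, surface_tol: float | None = None
) -> CPCCoordinate:
    """CPC coordinates of a surface point (inverse of :func:`cpc_forward`).

    Finds ``p_nz`` such that the coronal plane through AL, AR and the
    sagittal point at ``p_nz`` contains ``point`` (root of the signed plane
    distance, located by scan + bisection), then projects onto that coronal
    curve for ``p_al``. NZ and IZ map to the poles ``p_nz`` = 0 / 1.
    """
    point = np.asarray(point, dtype=float)
    if surface_tol is None:
        surface_tol = 3.0 * scalp.mean_edge_length
    d_surf, _ = scalp.vertex_tree.query(point)
    if d_surf > surface_tol:
        raise DataError(f"point is {d_surf:.1f} mm off the surface (tol {surface_tol:.1f})")
    snap = 1.5 * scalp.mean_edge_length
    if np.linalg.norm(point - scalp.nz) < snap:
        return CPCCoordinate(0.0, 0.5)
    if np.linalg.norm(point - scalp.iz) < snap:
        return CPCCoordinate(1.0, 0.5)

    sag = scalp.sagittal
    axis = scalp.ar - scalp.al

    def plane_dist(t: float) -> float:
        q = _point_at_fraction(sag, t)
        n = np.cross(axis, q - scalp.al)
        return float((point - scalp.al) @ _unit(n))

    ts = np.linspace(1e-4, 1 - 1e-4, 129)
    vals = np.array([plane_dist(t) for t in ts])
    candidates: list[tuple[float, float, float]] = []
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    for i in sign_changes:
        lo, hi = ts[i], ts[i + 1]
        flo = vals[i]
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            fmid = plane_dist(mid)
            if flo * fmid <= 0:
                hi = mid
            else:
                lo, flo = mid, fmid
        t_root = 0.5 * (lo + hi)
        coronal = _coronal_curve(scalp, _point_at_fraction(sag, t_root))
        p_al, dist = _project_fraction(coronal, point)
        candidates.append((dist, t_root, p_al))
    if not candidates:
        # no sign change: the point sits on a boundary coronal plane (e.g. the
        # equator near NZ/IZ); try the closest-plane parameters at both ends
        for i in np.argsort(np.abs(vals))[:3]:
            coronal = _coronal_curve(scalp, _point_at_fraction(sag, ts[int(i)]))
            p_al, dist = _project_fraction(coronal, point)
            candidates.append((dist, float(ts[int(i)]), p_al))
    dist, t_root, p_al = min(candidates)
    if dist > surface_tol:
        raise DataError("no coronal curve passes near the point")
    return CPCCoordinate(float(t_root), float(p_al))


def _surface_normal(scalp: ScalpMesh, point: np.ndarray) -> np.ndarray:
    """Outward unit normal: area-weighted faces of the nearest vertex's 1-ring."""
    _, vi = scalp.vertex_tree.query(point)
    face_ids = scalp.mesh.vertex_faces[vi]
    face_ids = face_ids[face_ids >= 0]
    normals = scalp.mesh.face_normals[face_ids]
    areas = scalp.mesh.area_faces[face_ids]
    n = _unit((normals * areas[:, None]).sum(axis=0))
    if n @ (point - scalp.landmark_centroid) < 0:
        n = -n
    return n


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis (right-hand rule)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def coil_frame(scalp: ScalpMesh, c: CPCCoordinate, theta_deg: float) -> CoilFrame:
    """Coil frame at CPC position ``c`` with handle rotated by ``theta_deg``.

    The 0-degree direction lies in the tangent plane, perpendicular to the
    intersection of the tangent plane with the plane through the position
    and both preauricular points, and points backward (toward IZ).
    Anticlockwise rotation viewed from outside the head is positive theta;
    clockwise is negative, so theta lives in (-180, 180].
    """
    if not (-180.0 < theta_deg <= 180.0):
        raise DataError(f"theta must lie in (-180, 180], got {theta_deg}")
    center = cpc_forward(scalp, c)
    normal = _surface_normal(scalp, center)
    m = np.cross(scalp.al - center, scalp.ar - center)
    if np.linalg.norm(m) < 1e-9:
        raise FrameUndefinedError("position is collinear with AL and AR")
    line = np.cross(normal, _unit(m))
    if np.linalg.norm(line) < 1e-9:
        raise FrameUndefinedError("tangent plane is parallel to the AL-AR plane")
    zero_dir = _unit(np.cross(normal, _unit(line)))
    back = scalp.iz - center
    back_t = back - (back @ normal) * normal
    if np.linalg.norm(back_t) < 1e-9:
        raise FrameUndefinedError("backward direction degenerates at this position")
    if zero_dir @ back_t < 0:
        zero_dir = -zero_dir
    handle = _rotate_about(zero_dir, normal, np.deg2rad(theta_deg))
    # clean residual numerical drift out of the tangent plane
    handle = _unit(handle - (handle @ normal) * normal)
    return CoilFrame(center=center, normal=normal, zero_dir=zero_dir, handle_dir=handle)


def coil_frames(
    scalp: ScalpMesh, c: CPCCoordinate, thetas_deg: "list[float] | np.ndarray"
) -> list[CoilFrame]:
    """Frames at one position for many orientations (shared surface solve).

    Equivalent to ``[coil_frame(scalp, c, t) for t in thetas_deg]`` but
    computes the position, normal and 0-degree direction once.
    """
    base = coil_frame(scalp, c, 0.0)
    out = []
    for theta in thetas_deg:
        if not (-180.0 < theta <= 180.0):
            raise DataError(f"theta must lie in (-180, 180], got {theta}")
        handle = _rotate_about(base.zero_dir, base.normal, np.deg2rad(theta))
        handle = _unit(handle - (handle @ base.normal) * base.normal)
        out.append(
            CoilFrame(
                center=base.center,
                normal=base.normal,
                zero_dir=base.zero_dir,
                handle_dir=handle,
            )
        )
    return out


def restore_placement_from_cortical_target(
    scalp: ScalpMesh, target: np.ndarray, max_angle_deg: float = 30.0
) -> CPCCoordinate:
    """CPC of the scalp point whose inward normal best points at ``target``.

    Ties in alignment angle (within 1e-6 rad) are broken by smaller
    Euclidean distance to the target, then by distance to the mean landmark
    position, then by vertex order — fully deterministic.
    """
    target = np.asarray(target, dtype=float)
    mesh = scalp.mesh
    # inside test for star-convex scalps: the target must lie behind the
    # outward normal of its nearest surface vertex
    _, vi_near = scalp.vertex_tree.query(target)
    n_near = _surface_normal(scalp, np.asarray(mesh.vertices[vi_near]))
    if (target - mesh.vertices[vi_near]) @ n_near > 1e-6:
        raise NotReachableError("cortical target lies outside the head surface")
    verts = np.asarray(mesh.vertices)
    # CPC parameterizes the scalp above the landmark plane; keep candidates there
    above = (verts - scalp.landmark_centroid) @ scalp.up >= 0
    if above.any():
        verts = verts[above]
    normals = np.asarray(mesh.vertex_normals)[above if above.any() else slice(None)].copy()
    flip = np.einsum("ij,ij->i", normals, verts - scalp.landmark_centroid) < 0
    normals[flip] = -normals[flip]
    to_target = target - verts
    dist = np.linalg.norm(to_target, axis=1)
    ok = dist > 1e-9
    cosang = np.full(len(verts), -1.0)
    cosang[ok] = np.einsum("ij,ij->i", -normals[ok], to_target[ok]) / (
        dist[ok] * np.linalg.norm(normals[ok], axis=1)
    )
    ang = np.arccos(np.clip(cosang, -1, 1))
    a_min = float(ang.min())
    if a_min > np.deg2rad(max_angle_deg):
        raise NotReachableError(
            f"best normal alignment {np.rad2deg(a_min):.1f} deg exceeds the "
            f"{max_angle_deg:.0f} deg cap"
        )
    cand = np.nonzero(ang <= a_min + 1e-6)[0]
    d = dist[cand]
    cand = cand[d <= d.min() + 1e-9]
    d2 = np.linalg.norm(verts[cand] - scalp.landmark_centroid, axis=1)
    cand = cand[d2 <= d2.min() + 1e-9]
    best = int(cand.min())
    return cpc_inverse(scalp, verts[best])
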