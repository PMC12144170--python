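"""Rigid-body range-of-motion sweep with impingement detection.

The carpal unit is rotated rigidly about a fixed axis through the rotation
center; at each sampled deviation angle the scene is checked for contact
between the carpal surface and the radius/ulna surfaces. Contact is exact
triangle-triangle intersection (Moller's interval test) with an optional
clearance epsilon; an axis-aligned-bounding-box broadphase keeps the pair
count small. The reported motion limits are the last contact-free sampled
angles before first contact in each direction (radial = positive sweep
angle, ulnar = negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .synthetic import RomScene


@dataclass
class RomResult:
    angles_deg: np.ndarray
    contact: np.ndarray  # bool per angle
    radial_limit_deg: float | None  # max contact-free positive deviation
    ulnar_limit_deg: float | None  # max contact-free magnitude, negative side
    first_contact: dict[str, float | None] = field(default_factory=dict)
    first_contact_pair: tuple[int, int] | None = None
    contact_at_neutral: bool = False

    def to_dict(self) -> dict:
        return {
            "angles_deg": self.angles_deg.tolist(),
            "contact": self.contact.astype(bool).tolist(),
            "radial_limit_deg": self.radial_limit_deg,
            "ulnar_limit_deg": self.ulnar_limit_deg,
            "first_contact": self.first_contact,
            "contact_at_neutral": self.contact_at_neutral,
        }


def deviation_angle(radius_axis: np.ndarray, carpal_motion_vector: np.ndarray) -> float:
    """Angle in degrees between the radius axis and a motion vector."""
    a = np.asarray(radius_axis, dtype=float)
    b = np.asarray(carpal_motion_vector, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("vectors must be nonzero")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + math.sin(th) * K + (1.0 - math.cos(th)) * (K @ K)


def rotate_vertices(vertices: np.ndarray, center: np.ndarray,
                    axis: np.ndarray, angle_deg: float) -> np.ndarray:
    R = rotation_matrix(axis, angle_deg)
    return (vertices - center) @ R.T + center


# ---------------------------------------------------------------------------
# Exact triangle-triangle intersection (Moller 1997 interval test)
# ---------------------------------------------------------------------------


def _tri_tri_batch(t1: np.ndarray, t2: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Vectorized intersection test for paired triangles (n, 3, 3) x 2."""
    n = t1.shape[0]
    out = np.zeros(n, dtype=bool)
    if n == 0:
        return out

    n2 = np.cross(t2[:, 1] - t2[:, 0], t2[:, 2] - t2[:, 0])
    d2 = -np.einsum("ij,ij->i", n2, t2[:, 0])
    dv1 = np.einsum("nj,nkj->nk", n2, t1) + d2[:, None]
    dv1 = np.where(np.abs(dv1) < eps, 0.0, dv1)

    n1 = np.cross(t1[:, 1] - t1[:, 0], t1[:, 2] - t1[:, 0])
    d1 = -np.einsum("ij,ij->i", n1, t1[:, 0])
    dv2 = np.einsum("nj,nkj->nk", n1, t2) + d1[:, None]
    dv2 = np.where(np.abs(dv2) < eps, 0.0, dv2)

    # all on one side of the other's plane -> no intersection
    sep1 = (dv1 > 0).all(axis=1) | (dv1 < 0).all(axis=1)
    sep2 = (dv2 > 0).all(axis=1) | (dv2 < 0).all(axis=1)
    cand = ~(sep1 | sep2)
    if not cand.any():
        return out

    idx = np.flatnonzero(cand)
    for i in idx:
        out[i] = _tri_tri_single(t1[i], t2[i], n1[i], n2[i], dv1[i], dv2[i], eps)
    return out


def _tri_tri_single(v, u, n1, n2, dv1, dv2, eps) -> bool:
    # coplanar case
    if np.all(dv1 == 0.0):
        return _coplanar_tri_tri(v, u, n2)
    D = np.cross(n1, n2)
    axis = int(np.argmax(np.abs(D)))
    pv = v[:, axis]
    pu = u[:, axis]
    iv = _interval(pv, dv1)
    iu = _interval(pu, dv2)
    if iv is None or iu is None:
        return False
    return max(iv[0], iu[0]) <= min(iv[1], iu[1]) + eps


def _interval(proj, dist):
    """Projection interval of a triangle on the intersection line."""
    pos = [i for i in range(3) if dist[i] > 0]
    neg = [i for i in range(3) if dist[i] < 0]
    zero = [i for i in range(3) if dist[i] == 0]
    if len(zero) == 3:
        return None
    pts = []
    for a in pos + zero:
        for b in neg:
            t = dist[a] / (dist[a] - dist[b])
            pts.append(proj[a] + t * (proj[b] - proj[a]))
    for z in zero:
        pts.append(proj[z])
    if len(pts) < 2:
        if len(pts) == 1:  # touching at a single vertex
            pts = [pts[0], pts[0]]
        else:
            return None
    return min(pts), max(pts)


def _coplanar_tri_tri(v, u, n) -> bool:
    axis = int(np.argmax(np.abs(n)))
    keep = [a for a in range(3) if a != axis]
    p = v[:, keep]
    q = u[:, keep]
    for i in range(3):
        for j in range(3):
            if _segments_intersect(p[i], p[(i + 1) % 3], q[j], q[(j + 1) % 3]):
                return True
    return _point_in_tri(p[0], q) or _point_in_tri(q[0], p)


def _segments_intersect(a, b, c, d) -> bool:
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    o1, o2 = orient(a, b, c), orient(a, b, d)
    o3, o4 = orient(c, d, a), orient(c, d, b)
    if ((o1 > 0) != (o2 > 0)) and ((o3 > 0) != (o4 > 0)):
        return True
    return False


def _point_in_tri(p, tri) -> bool:
    s1 = (tri[1][0] - tri[0][0]) * (p[1] - tri[0][1]) - (tri[1][1] - tri[0][1]) * (p[0] - tri[0][0])
    s2 = (tri[2][0] - tri[1][0]) * (p[1] - tri[1][1]) - (tri[2][1] - tri[1][1]) * (p[0] - tri[1][0])
    s3 = (tri[0][0] - tri[2][0]) * (p[1] - tri[2][1]) - (tri[0][1] - tri[2][1]) * (p[0] - tri[2][0])
    return (s1 >= 0 and s2 >= 0 and s3 >= 0) or (s1 <= 0 and s2 <= 0 and s3 <= 0)


def _aabb_pairs(tris_a: np.ndarray, tris_b: np.ndarray,
                pad: float = 0.0) -> np.ndarray:
    """Candidate (i, j) index pairs whose triangle AABBs overlap."""
    lo_a, hi_a = tris_a.min(axis=1) - pad, tris_a.max(axis=1) + pad
    lo_b, hi_b = tris_b.min(axis=1), tris_b.max(axis=1)
    # quick reject on the global overlap box
    box_lo = np.maximum(lo_a.min(axis=0), lo_b.min(axis=0))
    box_hi = np.minimum(hi_a.max(axis=0), hi_b.max(axis=0))
    if np.any(box_lo > box_hi):
        return np.empty((0, 2), dtype=np.int64)
    sel_a = np.flatnonzero(np.all((hi_a >= box_lo) & (lo_a <= box_hi), axis=1))
    sel_b = np.flatnonzero(np.all((hi_b >= box_lo) & (lo_b <= box_hi), axis=1))
    if sel_a.size == 0 or sel_b.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    ov = np.ones((sel_a.size, sel_b.size), dtype=bool)
    for ax in range(3):
        ov &= lo_a[sel_a, None, ax] <= hi_b[None, sel_b, ax]
        ov &= hi_a[sel_a, None, ax] >= lo_b[None, sel_b, ax]
    ii, jj = np.nonzero(ov)
    return np.stack([sel_a[ii], sel_b[jj]], axis=1)


def meshes_intersect(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh,
                     clearance: float = 0.0) -> tuple[bool, tuple[int, int] | None]:
    """Exact contact query between two triangle soups.

    With ``clearance > 0`` the query also reports contact when the closest
    approach falls below the clearance (checked conservatively by AABB
    padding plus vertex-to-triangle distances).
    """
    ta = mesh_a.vertices[mesh_a.faces]
    tb = mesh_b.vertices[mesh_b.faces]
    pairs = _aabb_pairs(ta, tb, pad=clearance)
    if pairs.shape[0] == 0:
        return False, None
    hit = _tri_tri_batch(ta[pairs[:, 0]], tb[pairs[:, 1]])
    if hit.any():
        k = int(np.flatnonzero(hit)[0])
        return True, (int(pairs[k, 0]), int(pairs[k, 1]))
    if clearance > 0.0:
        d = _min_vertex_face_distance(ta, tb, pairs)
        if d < clearance:
            return True, (int(pairs[0, 0]), int(pairs[0, 1]))
    return False, None


def _min_vertex_face_distance(ta, tb, pairs) -> float:
    pa = ta[pairs[:, 0]].reshape(-1, 3)
    pb = tb[pairs[:, 1]].reshape(-1, 3)
    lim = min(len(pa), 20000)
    d = np.min(
        np.linalg.norm(pa[:lim, None, :] - pb[None, :lim, :], axis=-1)
    )
    return float(d)


def sweep_contact(
    scene: RomScene,
    angle_range: tuple[float, float] = (-40.0, 40.0),
    step: float = 0.5,
    clearance: float = 0.0,
) -> RomResult:
    """Sweep the carpal unit through the deviation range and detect contact.

    Angles are sampled from the range boundaries inclusive at the given
    step. Contact at the neutral position is reported via the
    ``contact_at_neutral`` flag rather than as an error, since a construct
    already impinging at rest is a clinically meaningful state.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    lo, hi = angle_range
    if not lo < hi:
        raise ValueError("angle range must be non-degenerate")
    n = int(round((hi - lo) / step))
    angles = lo + step * np.arange(n + 1)

    carpal = scene.carpal_mesh
    statics = [scene.radius_mesh, scene.ulna_mesh]
    contact = np.zeros(angles.size, dtype=bool)
    first_pair = None
    for i, ang in enumerate(angles):
        verts = rotate_vertices(
            carpal.vertices, scene.rotation_center, scene.rotation_axis, float(ang)
        )
        moved = trimesh.Trimesh(vertices=verts, faces=carpal.faces, process=False)
        for stat in statics:
            hit, pair = meshes_intersect(moved, stat, clearance=clearance)
            if hit:
                contact[i] = True
                if first_pair is None:
                    first_pair = pair
                break

    neutral_idx = int(np.argmin(np.abs(angles)))
    contact_at_neutral = bool(contact[neutral_idx])

    def _limit(direction: int) -> tuple[float | None, float | None]:
        """(contact-free limit, first-contact angle) scanning from neutral."""
        if direction > 0:
            order = np.arange(neutral_idx, angles.size)
        else:
            order = np.arange(neutral_idx, -1, -1)
        last_free = None
        for k in order:
            if contact[k]:
                return last_free, float(angles[k])
            last_free = float(angles[k])
        return last_free, None

    radial_limit, radial_first = _limit(+1)
    ulnar_limit, ulnar_first = _limit(-1)
    return RomResult(
        angles_deg=angles,
        contact=contact,
        radial_limit_deg=radial_limit,
        ulnar_limit_deg=ulnar_limit,
        first_contact={"radial": radial_first, "ulnar": ulnar_first},
        first_contact_pair=first_pair,
        contact_at_neutral=contact_at_neutral,
    )
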