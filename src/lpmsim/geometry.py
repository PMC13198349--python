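"""Cylinder vs. closed-triangle-mesh solid-overlap predicates.

A "collision" is solid-solid overlap with no minimum-penetration threshold:
tissues are treated as rigid and any contact counts. The device is a right
circular cylinder with flat caps. The decision is the union of

  (a) surface test - any (non-excluded) face comes within ``radius`` of the
      axis segment with the closest triangle point between the two end-cap
      planes, or the face crosses a cap plane within the cap disc;
  (b) containment test - the axis midpoint lies inside the mesh solid
      (cylinder partially or fully swallowed);
  (c) piercing test - any mesh vertex lies inside the cylinder solid
      (thin structure poking in between faces).

All kernels are batched numpy; an independent Monte-Carlo sampling oracle
(:func:`overlap_oracle`) is provided for verification and is never used by
the predicate itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .mesh_io import MeshValidationError, TriangleMesh

#: absolute tolerance for all distance comparisons, in mm
DIST_TOL = 1e-6

_EPS = 1e-12


@dataclass
class Cylinder:
    """Flat-capped right circular cylinder: the leadless-device model.

    ``base`` is the implant-surface end; ``axis`` points into the cavity.
    """

    base: np.ndarray
    axis: np.ndarray
    length: float
    radius: float

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, float).reshape(3)
        self.axis = np.asarray(self.axis, float).reshape(3)
        n = np.linalg.norm(self.axis)
        if abs(n - 1.0) > 1e-9:
            if n < _EPS:
                raise ValueError("cylinder axis must be a nonzero vector")
            self.axis = self.axis / n
        if self.length < 0 or self.radius < 0:
            raise ValueError("cylinder length and radius must be non-negative")

    @property
    def tip(self) -> np.ndarray:
        return self.base + self.length * self.axis

    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Two unit vectors orthogonal to the axis (and to each other)."""
        a = self.axis
        ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(a, ref)
        u /= np.linalg.norm(u)
        return u, np.cross(a, u)

    def contains_points(self, points: np.ndarray, tol: float = DIST_TOL) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float)) - self.base
        ax = p @ self.axis
        rad2 = np.einsum("ij,ij->i", p, p) - ax**2
        return (
            (ax >= -tol)
            & (ax <= self.length + tol)
            & (rad2 <= (self.radius + tol) ** 2)
        )

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform samples from the solid cylinder."""
        u, v = self.frame()
        z = rng.uniform(0.0, self.length, n)
        r = self.radius * np.sqrt(rng.uniform(0.0, 1.0, n))
        th = rng.uniform(0.0, 2 * np.pi, n)
        return (
            self.base[None, :]
            + z[:, None] * self.axis[None, :]
            + (r * np.cos(th))[:, None] * u[None, :]
            + (r * np.sin(th))[:, None] * v[None, :]
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Cylinder":
        r = np.asarray(rotation, float)
        return Cylinder(r @ self.base + np.asarray(translation, float),
                        r @ self.axis, self.length, self.radius)


@dataclass
class OverlapResult:
    collides: bool
    witness: np.ndarray | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.collides


# ------------------------------------------------------------------ batched kernels


def _dot(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.einsum("...i,...i->...", a, b)


def _closest_point_on_triangle(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each point (pairwise, K x 3)."""
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = _dot(ab, ap), _dot(ac, ap)
    bp = p - b
    d3, d4 = _dot(ab, bp), _dot(ac, bp)
    cp = p - c
    d5, d6 = _dot(ab, cp), _dot(ac, cp)

    out = np.empty_like(np.broadcast_arrays(p, a)[0])
    done = np.zeros(out.shape[:-1], dtype=bool)

    def settle(mask, value):
        nonlocal done
        m = mask & ~done
        out[m] = value[m] if value.shape == out.shape else np.broadcast_to(value, out.shape)[m]
        done = done | m

    settle((d1 <= 0) & (d2 <= 0), a)
    settle((d3 >= 0) & (d4 <= d3), b)
    vc = d1 * d4 - d3 * d2
    t_ab = d1 / np.where(np.abs(d1 - d3) > _EPS, d1 - d3, 1.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t_ab[..., None] * ab)
    settle((d6 >= 0) & (d5 <= d6), c)
    vb = d5 * d2 - d1 * d6
    t_ac = d2 / np.where(np.abs(d2 - d6) > _EPS, d2 - d6, 1.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t_ac[..., None] * ac)
    va = d3 * d6 - d5 * d4
    den_bc = (d4 - d3) + (d5 - d6)
    t_bc = (d4 - d3) / np.where(np.abs(den_bc) > _EPS, den_bc, 1.0)
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + t_bc[..., None] * (c - b))
    den = va + vb + vc
    inv = 1.0 / np.where(np.abs(den) > _EPS, den, 1.0)
    settle(np.ones_like(done), a + (vb * inv)[..., None] * ab + (vc * inv)[..., None] * ac)
    return out


def _segseg_closest(p1, q1, p2, q2) -> tuple[np.ndarray, np.ndarray]:
    """Closest points between segments [p1,q1] and [p2,q2] (pairwise)."""
    d1, d2, r = q1 - p1, q2 - p2, p1 - p2
    a, e, f = _dot(d1, d1), _dot(d2, d2), _dot(d2, r)
    c = _dot(d1, r)
    b = _dot(d1, d2)
    denom = a * e - b * b
    s = np.where(denom > _EPS, np.clip((b * f - c * e) / np.where(denom > _EPS, denom, 1.0), 0, 1), 0.0)
    e_safe = np.where(e > _EPS, e, 1.0)
    t = np.where(e > _EPS, (b * s + f) / e_safe, 0.0)
    t_cl = np.clip(t, 0.0, 1.0)
    a_safe = np.where(a > _EPS, a, 1.0)
    s = np.where(t != t_cl, np.clip((t_cl * b - c) / a_safe, 0.0, 1.0), s)
    s = np.where(a > _EPS, s, 0.0)
    return p1 + s[..., None] * d1, p2 + t_cl[..., None] * d2


def _segment_triangle_intersect(a0, a1, tri, tol=1e-12):
    """Moller-Trumbore segment/triangle intersection (pairwise).

    Returns (hit, point); for non-hits the point is unspecified.
    """
    t0, t1, t2 = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    e1, e2 = t1 - t0, t2 - t0
    d = a1 - a0
    h = np.cross(d, e2)
    det = _dot(e1, h)
    ok = np.abs(det) > tol
    inv = 1.0 / np.where(ok, det, 1.0)
    s = a0 - t0
    u = _dot(s, h) * inv
    q = np.cross(s, e1)
    v = _dot(d, q) * inv
    t = _dot(e2, q) * inv
    hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol) & (t >= -tol) & (t <= 1 + tol)
    return hit, a0 + t[..., None] * d


def _segment_triangle_closest(a0: np.ndarray, a1: np.ndarray, tri: np.ndarray):
    """Min distance between segment and triangle, pairwise.

    Returns ``(dist, p_tri)`` where ``p_tri`` is the closest point on the
    triangle. Exact: the minimum is attained either at a proper
    intersection, at a segment endpoint vs. the triangle, or between the
    segment and a triangle edge.
    """
    hit, x = _segment_triangle_intersect(a0, a1, tri)

    qa = _closest_point_on_triangle(a0, tri)
    qb = _closest_point_on_triangle(a1, tri)
    cand_pts = [qa, qb]
    cand_d2 = [_dot(a0 - qa, a0 - qa), _dot(a1 - qb, a1 - qb)]
    for i, j in ((0, 1), (1, 2), (2, 0)):
        cseg, cedge = _segseg_closest(a0, a1, tri[..., i, :], tri[..., j, :])
        cand_pts.append(cedge)
        cand_d2.append(_dot(cseg - cedge, cseg - cedge))
    d2 = np.stack(cand_d2, axis=-1)
    idx = np.argmin(d2, axis=-1)
    pts = np.stack(cand_pts, axis=-2)
    p_tri = np.take_along_axis(pts, idx[..., None, None], axis=-2)[..., 0, :]
    dist = np.sqrt(np.take_along_axis(d2, idx[..., None], axis=-1)[..., 0])
    dist = np.where(hit, 0.0, dist)
    p_tri = np.where(hit[..., None], x, p_tri)
    return dist, p_tri


def segment_triangle_distance(a: Sequence[float], b: Sequence[float],
                              tri: np.ndarray) -> float:
    """Exact minimum Euclidean distance (mm) between segment ab and a triangle."""
    a0 = np.asarray(a, float).reshape(1, 3)
    a1 = np.asarray(b, float).reshape(1, 3)
    t = np.asarray(tri, float).reshape(1, 3, 3)
    d, _ = _segment_triangle_closest(a0, a1, t)
    return float(d[0])


# --------------------------------------------------------------- point containment


def points_in_mesh(points: np.ndarray, mesh: TriangleMesh,
                   rng_seed: int = 0) -> np.ndarray:
    """Ray-parity interior test for a batch of points against a closed mesh.

    Degenerate rays (grazing an edge/vertex or running parallel through a
    face plane) are detected via barycentric margins and re-cast along a
    different direction.
    """
    if not mesh.is_closed():
        raise MeshValidationError("point-in-mesh test requires a closed mesh")
    pts = np.atleast_2d(np.asarray(points, float))
    tri = mesh.triangles  # (M, 3, 3)
    n = len(pts)
    result = np.zeros(n, dtype=bool)
    pending = np.arange(n)
    rng = np.random.default_rng(rng_seed)
    direction = np.array([0.57735027, 0.57735027, 0.57735027])
    for attempt in range(12):
        if not len(pending):
            break
        p = pts[pending]  # (P, 3)
        t0, t1, t2 = tri[:, 0], tri[:, 1], tri[:, 2]
        e1, e2 = t1 - t0, t2 - t0
        h = np.cross(direction, e2)  # (M, 3)
        det = np.einsum("mi,mi->m", e1, h)
        ok = np.abs(det) > 1e-12
        inv = 1.0 / np.where(ok, det, 1.0)
        s = p[:, None, :] - t0[None, :, :]  # (P, M, 3)
        u = np.einsum("pmi,mi->pm", s, h) * inv
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("pmi,i->pm", q, direction) * inv
        t = np.einsum("pmi,mi->pm", q, e2) * inv
        w = 1.0 - u - v
        inside = ok[None, :] & (u >= 0) & (v >= 0) & (w >= 0) & (t > 0)
        margin = np.minimum(np.minimum(np.abs(u), np.abs(v)),
                            np.minimum(np.abs(w), np.abs(t)))
        suspicious = (
            (ok[None, :] & (margin < 1e-9) & (u > -1e-7) & (v > -1e-7) & (w > -1e-7) & (t > -1e-7))
            | (~ok[None, :] & (np.abs(np.einsum("pmi,mi->pm", s, np.cross(e1, e2))) < 1e-7))
        ).any(axis=1)
        parity = (inside.sum(axis=1) % 2).astype(bool)
        good = ~suspicious
        result[pending[good]] = parity[good]
        pending = pending[suspicious]
        d = rng.normal(size=3)
        direction = d / np.linalg.norm(d)
    if len(pending):  # give up on perturbation; accept last parity
        result[pending] = parity[suspicious]
    return result


def point_in_closed_mesh(p: Sequence[float], mesh: TriangleMesh) -> bool:
    """True iff ``p`` is interior to the closed mesh (ray-parity rule)."""
    return bool(points_in_mesh(np.asarray(p, float).reshape(1, 3), mesh)[0])


# --------------------------------------------------------------------- overlap test


def _point_segment_distance_2pt(c, x1, x2):
    """Distance from points c to segments [x1, x2] (pairwise)."""
    d = x2 - x1
    dd = _dot(d, d)
    t = np.clip(_dot(c - x1, d) / np.where(dd > _EPS, dd, 1.0), 0.0, 1.0)
    t = np.where(dd > _EPS, t, 0.0)
    q = x1 + t[..., None] * d
    return np.sqrt(_dot(c - q, c - q))


def _cap_disc_hits(centers, axes, radius, tri, tol=DIST_TOL):
    """Does each triangle cross the cap plane within the cap disc? (pairwise)

    ``centers``/``axes`` per pair; the cap plane passes through the center
    with the axis as its normal. The triangle/plane intersection segment is
    built from edge crossings and on-plane vertices; the test is whether it
    comes within ``radius`` of the center.
    """
    h = _dot(tri - centers[..., None, :], axes[..., None, :])  # (K, 3)
    on_plane = np.abs(h) <= tol
    coplanar = on_plane.all(axis=-1)
    straddle = (h.min(axis=-1) < -tol) & (h.max(axis=-1) > tol)

    # candidate points on the plane: 3 possible edge crossings + 3 vertices
    cands = np.zeros(tri.shape[:-2] + (6, 3))
    valid = np.zeros(tri.shape[:-2] + (6,), dtype=bool)
    for k, (i, j) in enumerate(((0, 1), (1, 2), (2, 0))):
        hi, hj = h[..., i], h[..., j]
        cross = (hi * hj) < -(tol * tol)
        denom = np.where(np.abs(hi - hj) > _EPS, hi - hj, 1.0)
        t = hi / denom
        cands[..., k, :] = tri[..., i, :] + t[..., None] * (tri[..., j, :] - tri[..., i, :])
        valid[..., k] = cross
    for k in range(3):
        cands[..., 3 + k, :] = tri[..., k, :]
        valid[..., 3 + k] = on_plane[..., k]

    any_valid = valid.any(axis=-1) & (straddle | on_plane.any(axis=-1)) & ~coplanar
    # the intersection is the segment between the two extreme candidates
    big = 1e30
    w = np.where(valid, 1.0, 0.0)
    nv = np.maximum(w.sum(axis=-1), 1.0)
    mean = (cands * w[..., None]).sum(axis=-2) / nv[..., None]
    off = np.where(valid[..., None], cands - mean[..., None, :], 0.0)
    far = np.argmax(_dot(off, off), axis=-1)
    u = np.take_along_axis(off, far[..., None, None], axis=-2)[..., 0, :]
    un = np.linalg.norm(u, axis=-1, keepdims=True)
    u = u / np.where(un > _EPS, un, 1.0)
    proj = _dot(cands - mean[..., None, :], u[..., None, :])
    proj = np.where(valid, proj, big)
    x1 = np.take_along_axis(cands, np.argmin(proj, axis=-1)[..., None, None], axis=-2)[..., 0, :]
    proj = np.where(valid, _dot(cands - mean[..., None, :], u[..., None, :]), -big)
    x2 = np.take_along_axis(cands, np.argmax(proj, axis=-1)[..., None, None], axis=-2)[..., 0, :]
    seg_d = _point_segment_distance_2pt(centers, x1, x2)
    hits = any_valid & (seg_d <= radius + tol)

    if coplanar.any():
        cp = _closest_point_on_triangle(centers, tri)
        d_cop = np.sqrt(_dot(centers - cp, centers - cp))
        hits = hits | (coplanar & (d_cop <= radius + tol))
    return hits


def _overlap_batch(
    bases: np.ndarray,
    axes: np.ndarray,
    length: float,
    radius: float,
    mesh: TriangleMesh,
    *,
    static_excluded_faces: np.ndarray | None = None,
    exclusion_radius: float = 0.0,
    tri_cache: dict | None = None,
    chunk: int = 400_000,
    with_witness: bool = False,
):
    """Vectorized overlap decision for N cylinders of shared length/radius.

    ``static_excluded_faces`` is a boolean face mask dropped from the
    surface tests; ``exclusion_radius`` additionally drops, per cylinder,
    faces (and the vertices used only by them) whose centroid lies within
    that distance of the cylinder base. Containment (test b) always uses the
    full solid.
    """
    bases = np.atleast_2d(np.asarray(bases, float))
    axes = np.atleast_2d(np.asarray(axes, float))
    n_sites = len(bases)
    if tri_cache is None:
        tri_cache = {}
    if "tris" not in tri_cache:
        tri_cache["tris"] = mesh.triangles
        tri_cache["centroids"] = tri_cache["tris"].mean(axis=1)
        tri_cache["circum"] = np.linalg.norm(
            tri_cache["tris"] - tri_cache["centroids"][:, None, :], axis=2
        ).max(axis=1)
    tris = tri_cache["tris"]
    cents = tri_cache["centroids"]
    circum = tri_cache["circum"]

    tips = bases + length * axes
    mids = bases + 0.5 * length * axes

    collides = np.zeros(n_sites, dtype=bool)
    witness = [None] * n_sites if with_witness else None

    # --- (b) axis midpoint containment (full solid, never excluded) -------------
    inside = points_in_mesh(mids, mesh)
    collides |= inside
    if with_witness:
        for i in np.flatnonzero(inside):
            witness[i] = mids[i]

    # --- (c) mesh vertices piercing the cylinder --------------------------------
    v = mesh.vertices
    vert_ok = np.ones(len(v), dtype=bool)
    if static_excluded_faces is not None and static_excluded_faces.any():
        used = np.zeros(len(v), dtype=bool)
        used[np.unique(mesh.faces[~static_excluded_faces])] = True
        vert_ok &= used
    rel = v[None, :, :] - bases[:, None, :]  # (N, V, 3)
    ax = np.einsum("nvi,ni->nv", rel, axes)
    rad2 = np.einsum("nvi,nvi->nv", rel, rel) - ax**2
    in_cyl = (ax >= -DIST_TOL) & (ax <= length + DIST_TOL) & (
        rad2 <= (radius + DIST_TOL) ** 2
    )
    in_cyl &= vert_ok[None, :]
    if exclusion_radius > 0:
        dv = np.linalg.norm(v[None, :, :] - bases[:, None, :], axis=2)
        in_cyl &= dv >= exclusion_radius
    hit_c = in_cyl.any(axis=1)
    if with_witness:
        for i in np.flatnonzero(hit_c & ~collides):
            witness[i] = v[np.argmax(in_cyl[i])]
    collides |= hit_c

    # --- (a) surface test: candidate pair prefilter ------------------------------
    face_ok = np.ones(len(tris), dtype=bool)
    if static_excluded_faces is not None:
        face_ok &= ~static_excluded_faces
    reach = 0.5 * length + radius + circum + 1e-3  # (M,)
    d_mid = np.linalg.norm(cents[None, :, :] - mids[:, None, :], axis=2)
    cand = (d_mid <= reach[None, :]) & face_ok[None, :]
    if exclusion_radius > 0:
        d_base = np.linalg.norm(cents[None, :, :] - bases[:, None, :], axis=2)
        cand &= d_base >= exclusion_radius
    cand &= ~collides[:, None]

    si, fi = np.nonzero(cand)
    for lo in range(0, len(si), chunk):
        hi = min(lo + chunk, len(si))
        s, f = si[lo:hi], fi[lo:hi]
        if not len(s):
            continue
        t = tris[f]
        d, p_tri = _segment_triangle_closest(bases[s], tips[s], t)
        near = d <= radius + DIST_TOL
        axial = _dot(p_tri - bases[s], axes[s])
        in_band = (axial >= -DIST_TOL) & (axial <= length + DIST_TOL)
        hit = near & in_band
        # cap test for near faces whose closest point falls outside the band
        need_cap = near & ~hit
        if need_cap.any():
            ks = np.flatnonzero(need_cap)
            for center in (bases, tips):
                ch = _cap_disc_hits(center[s[ks]], axes[s[ks]], radius, t[ks])
                hit[ks[ch]] = True
        if hit.any():
            hit_sites = s[hit]
            if with_witness:
                for idx, site in enumerate(hit_sites):
                    if witness[site] is None:
                        witness[site] = p_tri[hit][idx]
            collides[hit_sites] = True
    return (collides, witness) if with_witness else (collides, None)


def cylinder_mesh_overlap(
    cyl: Cylinder,
    mesh: TriangleMesh,
    excluded_faces: Iterable[int] = (),
) -> OverlapResult:
    """Do the cylinder solid and the closed mesh solid intersect?

    ``excluded_faces`` are dropped from the surface-crossing tests only
    (the attachment-site self-intersection rule); the containment test
    always sees the full solid.
    """
    if not mesh.is_closed():
        raise MeshValidationError("overlap test requires a closed mesh")
    mask = None
    excluded = np.fromiter(excluded_faces, dtype=np.int64)
    if excluded.size:
        if excluded.min() < 0 or excluded.max() >= len(mesh.faces):
            raise ValueError("excluded_faces contains invalid face indices")
        mask = np.zeros(len(mesh.faces), dtype=bool)
        mask[excluded] = True
    hit, wit = _overlap_batch(
        cyl.base[None, :], cyl.axis[None, :], cyl.length, cyl.radius, mesh,
        static_excluded_faces=mask, with_witness=True,
    )
    return OverlapResult(bool(hit[0]), None if wit[0] is None else np.asarray(wit[0]))


def overlap_oracle(cyl: Cylinder, mesh: TriangleMesh, n_samples: int = 2000,
                   seed: int = 0) -> bool:
    """Monte-Carlo overlap oracle, independent of the analytic predicate.

    Draws uniform samples in the cylinder solid (tested against the mesh)
    and in the mesh solid via rejection sampling in its bounding box
    (tested against the cylinder). Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    if cyl.length > 0 and cyl.radius > 0:
        pts = cyl.sample_points(n_samples, rng)
        if points_in_mesh(pts, mesh, rng_seed=seed + 1).any():
            return True
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    accepted = 0
    for _ in range(200):
        if accepted >= n_samples:
            break
        box = rng.uniform(lo, hi, size=(max(n_samples, 256), 3))
        ins = points_in_mesh(box, mesh, rng_seed=seed + 2)
        inside_pts = box[ins]
        accepted += len(inside_pts)
        if len(inside_pts) and cyl.contains_points(inside_pts, tol=0.0).any():
            return True
    return False
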