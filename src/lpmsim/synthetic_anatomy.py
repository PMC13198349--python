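"""Parameterized dynamic right-ventricle anatomies.

The generator emulates the dilated, heart-failure RV the collision analysis
assumes: a D-shaped cavity (flat septal wall, bulging free wall) tapering to
the apex and widest at the base, a 3.5-mm free-wall shell, a 2-mm tricuspid
annulus slab with a cone of valve structures hanging from the papillary-
muscle chordae points, three papillary muscles plus a moderator band, and a
10-phase contraction whose amplitude is calibrated by root finding so the
cavity reaches a prescribed ejection fraction exactly.

Geometry conventions: the long axis is z, apex at the origin, basal (TV
annulus) plane at ``z = long_axis_length``; the septum is the planar sector
``x = 0`` and the cavity bulges into ``x > 0``. Units are millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.optimize import brentq

from .mesh_io import (
    LabeledScene,
    MeshValidationError,
    SceneSequence,
    StructureCategory,
    TriangleMesh,
    closed_mesh_volume,
)
from .geometry import points_in_mesh

CAT = StructureCategory


@dataclass(frozen=True)
class PMSpec:
    """One papillary muscle: a tapered cone from a wall attachment.

    ``kind`` is "free_wall" (attachment parameterized by ``angle_deg``, the
    azimuth of the free-wall half-ellipse, -90..90) or "septum" (attachment
    parameterized by ``y_frac``, the fractional chord position). The tip --
    the basal-most point -- is the chordae tendineae attachment point.
    """

    name: str
    kind: str  # "free_wall" | "septum"
    z_frac: float
    base_radius: float
    height: float
    angle_deg: float = 0.0
    y_frac: float = 0.0


@dataclass(frozen=True)
class BandSpec:
    """Moderator band: a capsule strut from the septum to the free wall."""

    septal_y_frac: float = -0.20
    septal_z_frac: float = 0.28
    wall_angle_deg: float = 55.0
    wall_z_frac: float = 0.33
    radius: float = 3.0


def default_pm_specs() -> tuple[PMSpec, ...]:
    return (
        PMSpec("anterior_pm", "free_wall", 0.42, 4.5, 22.0, angle_deg=55.0),
        PMSpec("inferior_pm", "free_wall", 0.38, 4.5, 22.0, angle_deg=-55.0),
        PMSpec("septal_pm", "septum", 0.33, 4.0, 18.0, y_frac=-0.15),
    )


@dataclass
class AnatomyConfig:
    """Anatomy and motion parameters (mm, mL, %, counts).

    Defaults describe the dilated heart-failure RV of the calibration
    cohort: end-diastolic volume 283 mL, ejection fraction 22%, a 3.5 mm
    free-wall shell and a 2 mm tricuspid annulus plane.
    """

    edv_target: float = 283.0
    ef_target: float = 22.0
    n_phases: int = 10
    wall_thickness: float = 3.5
    tv_plane_thickness: float = 2.0
    long_axis_length: float = 95.0
    depth_ratio: float = 1.25  # cavity depth (x) semi-axis / width (y) semi-axis
    taper_exponent: float = 0.85  # apex-to-base radius profile (z/L)^p
    annulus_radius: float | None = None  # derived from basal width if None
    longitudinal_ratio: float = 0.5  # longitudinal vs radial contraction
    pm_specs: tuple[PMSpec, ...] = field(default_factory=default_pm_specs)
    moderator_band: BandSpec | None = field(default_factory=BandSpec)
    n_circ: int = 32  # circumferential samples per ring (even)
    n_long: int = 16  # long-axis levels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edv_target <= 0:
            raise ValueError("edv_target must be positive")
        if not (0 <= self.ef_target < 100):
            raise ValueError("ef_target must be in [0, 100)")
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.wall_thickness <= 0 or self.tv_plane_thickness <= 0:
            raise ValueError("thicknesses must be positive")
        if self.n_circ % 2 or self.n_circ < 8:
            raise ValueError("n_circ must be even and >= 8")


@dataclass
class EDScene:
    """End-diastolic scene plus the generator's bookkeeping."""

    scene: LabeledScene
    chordae_points: dict[str, np.ndarray]
    conduction_paths: dict[str, np.ndarray]
    septal_node_ids: np.ndarray  # endocardial-face vertex ids in the SEPTUM mesh
    septal_faces: np.ndarray  # endocardial faces (indices into SEPTUM vertices)
    semi_axes: tuple[float, float]  # (depth a, width b)


@dataclass
class PatientAnatomy:
    patient_id: str
    config: AnatomyConfig
    sequence: SceneSequence
    landmarks: dict[str, np.ndarray]
    chordae_points: dict[str, np.ndarray]
    conduction_paths: dict[str, np.ndarray]
    septal_node_ids: np.ndarray
    septal_faces: np.ndarray


# ------------------------------------------------------------------ mesh building


def _profile(z: np.ndarray, L: float, p: float) -> np.ndarray:
    return np.clip(np.asarray(z, float) / L, 0.0, 1.0) ** p


def _grid_faces(n_rows: int, n_cols: int, apex_index: int, row0: int,
                wrap: bool = False) -> np.ndarray:
    """Triangulate a (rows x cols) vertex grid plus an apex fan below row 0.

    Vertex id of (row r, col c) is ``row0 + r * n_cols + c``.
    """
    faces = []
    cols = n_cols if wrap else n_cols - 1
    for c in range(cols):
        c2 = (c + 1) % n_cols
        faces.append((apex_index, row0 + c2, row0 + c))  # wound like the quads
    for r in range(n_rows - 1):
        for c in range(cols):
            c2 = (c + 1) % n_cols
            v00 = row0 + r * n_cols + c
            v01 = row0 + r * n_cols + c2
            v10 = row0 + (r + 1) * n_cols + c
            v11 = row0 + (r + 1) * n_cols + c2
            faces.append((v00, v01, v11))
            faces.append((v00, v11, v10))
    return np.array(faces, dtype=np.int64)


def _extrude_patch(vertices: np.ndarray, faces: np.ndarray,
                   offsets: np.ndarray) -> TriangleMesh:
    """Close an open surface patch into a solid slab/shell.

    The patch is duplicated at ``vertices + offsets`` and stitched along its
    boundary; the inner copy is flipped so the winding is globally
    consistent, and the result is re-oriented to positive volume.
    """
    n = len(vertices)
    outer = vertices + offsets
    inner_faces = faces[:, ::-1]
    outer_faces = faces + n
    # directed boundary edges (appear exactly once in the patch orientation)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = {}
    for u, v in map(tuple, edges):
        key[(u, v)] = key.get((u, v), 0) + 1
    rim = []
    for (u, v), cnt in key.items():
        if cnt == 1 and key.get((v, u), 0) == 0:
            rim.append((u, v, v + n))
            rim.append((u, v + n, u + n))
    all_faces = np.concatenate([inner_faces, outer_faces, np.array(rim, np.int64)])
    mesh = TriangleMesh(np.concatenate([vertices, outer]), all_faces)
    t = mesh.triangles
    signed = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum()
    if signed < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def _patch_vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    t = vertices[faces]
    fn = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])  # area-weighted
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    nrm = np.linalg.norm(vn, axis=1, keepdims=True)
    return vn / np.where(nrm > 1e-12, nrm, 1.0)


def _hull_mesh(points: np.ndarray) -> TriangleMesh:
    hull = trimesh.convex.convex_hull(points)
    return TriangleMesh(np.asarray(hull.vertices, float), np.asarray(hull.faces))


def _circle(center: np.ndarray, axis: np.ndarray, radius: float, n: int = 14) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0, 0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1, 0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return center + radius * (np.outer(np.cos(th), u) + np.outer(np.sin(th), v))


def _cone(base_center, axis_dir, base_radius, tip) -> TriangleMesh:
    return _hull_mesh(np.vstack([_circle(base_center, axis_dir, base_radius), tip]))


def _capsule(p0, p1, radius) -> TriangleMesh:
    axis = np.asarray(p1, float) - np.asarray(p0, float)
    return _hull_mesh(np.vstack([_circle(p0, axis, radius), _circle(p1, axis, radius)]))


def _concat(meshes: list[TriangleMesh], label: CAT) -> TriangleMesh:
    verts, faces, off = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        off += len(m.vertices)
    return TriangleMesh(np.concatenate(verts), np.concatenate(faces), label)


class _Frame:
    """Analytic description of the cavity cross-sections."""

    def __init__(self, a: float, b: float, cfg: AnatomyConfig):
        self.a, self.b, self.cfg = a, b, cfg
        self.L = cfg.long_axis_length

    def radii(self, z: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = _profile(z, self.L, self.cfg.taper_exponent)
        return self.a * f, self.b * f

    def free_wall_point(self, angle_deg: float, z: float) -> np.ndarray:
        rx, ry = self.radii(z)
        th = math.radians(angle_deg)
        return np.array([rx * math.cos(th), ry * math.sin(th), z])

    def septal_point(self, y_frac: float, z: float) -> np.ndarray:
        _, ry = self.radii(z)
        return np.array([0.0, y_frac * ry, z])


def _cavity_mesh(frame: _Frame, cfg: AnatomyConfig) -> TriangleMesh:
    """Closed cavity surface (free wall + septum + basal cap)."""
    m, half = cfg.n_circ, cfg.n_circ // 2
    L = cfg.long_axis_length
    zs = L * np.arange(1, cfg.n_long + 1) / cfg.n_long
    rings = []
    for z in zs:
        rx, ry = frame.radii(z)
        th = -np.pi / 2 + np.pi * np.arange(half + 1) / half
        fw = np.column_stack([rx * np.cos(th), ry * np.sin(th), np.full(half + 1, z)])
        yc = ry * (1 - 2 * np.arange(1, half) / half)
        sep = np.column_stack([np.zeros(half - 1), yc, np.full(half - 1, z)])
        rings.append(np.vstack([fw, sep]))
    verts = np.vstack([[[0.0, 0.0, 0.0]]] + rings)
    faces = _grid_faces(cfg.n_long, m, apex_index=0, row0=1, wrap=True)
    # basal cap: fan to the ring centroid
    top0 = 1 + (cfg.n_long - 1) * m
    cap_center = verts[top0 : top0 + m].mean(axis=0)
    cap_id = len(verts)
    verts = np.vstack([verts, cap_center])
    cap = []
    for c in range(m):
        c2 = (c + 1) % m
        cap.append((cap_id, top0 + c, top0 + c2))
    mesh = TriangleMesh(verts, np.vstack([faces, np.array(cap, np.int64)]), CAT.CAVITY)
    t = mesh.triangles
    if np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def _septum_slab(frame: _Frame, cfg: AnatomyConfig):
    """Closed septal slab; returns (mesh, endocardial node ids, endo faces)."""
    half = cfg.n_circ // 2
    L = cfg.long_axis_length
    zs = L * np.arange(1, cfg.n_long + 1) / cfg.n_long
    rows = []
    for z in zs:
        _, ry = frame.radii(z)
        yc = ry * (1 - 2 * np.arange(half + 1) / half)  # +ry .. -ry
        rows.append(np.column_stack([np.zeros(half + 1), yc, np.full(half + 1, z)]))
    verts = np.vstack([[[0.0, 0.0, 0.0]]] + rows)
    faces = _grid_faces(cfg.n_long, half + 1, apex_index=0, row0=1, wrap=False)
    # endocardial normal is +x; the slab extrudes into the septum (-x)
    offsets = np.tile([-cfg.wall_thickness, 0.0, 0.0], (len(verts), 1))
    mesh = _extrude_patch(verts, faces, offsets)
    mesh.label = CAT.SEPTUM
    return mesh, np.arange(len(verts)), faces


def _free_wall_shell(frame: _Frame, cfg: AnatomyConfig) -> TriangleMesh:
    half = cfg.n_circ // 2
    L = cfg.long_axis_length
    zs = L * np.arange(1, cfg.n_long + 1) / cfg.n_long
    rows = []
    for z in zs:
        rx, ry = frame.radii(z)
        th = -np.pi / 2 + np.pi * np.arange(half + 1) / half
        rows.append(np.column_stack([rx * np.cos(th), ry * np.sin(th),
                                     np.full(half + 1, z)]))
    verts = np.vstack([[[0.0, 0.0, 0.0]]] + rows)
    faces = _grid_faces(cfg.n_long, half + 1, apex_index=0, row0=1, wrap=False)
    normals = _patch_vertex_normals(verts, faces)
    # orient away from the cavity interior
    interior = np.array([0.3 * frame.a, 0.0, 0.5 * L])
    outward = np.einsum("ij,ij->i", normals, verts - interior)
    normals[outward < 0] *= -1.0
    mesh = _extrude_patch(verts, faces, cfg.wall_thickness * normals)
    mesh.label = CAT.RV_WALL
    return mesh


def _annulus_geometry(frame: _Frame, cfg: AnatomyConfig) -> tuple[np.ndarray, float]:
    rx_b, ry_b = frame.radii(cfg.long_axis_length)
    radius = cfg.annulus_radius if cfg.annulus_radius is not None else 0.30 * ry_b
    center = np.array([radius + 4.0, 0.0, cfg.long_axis_length])
    # the ring must fit inside the basal cross-section
    if center[0] + radius > rx_b or (center[0] / rx_b) ** 2 + (radius / ry_b) ** 2 > 1:
        raise ValueError(
            f"annulus radius {radius:.1f} mm does not fit the basal cavity "
            f"cross-section (depth {rx_b:.1f}, half-width {ry_b:.1f} mm)"
        )
    return center, float(radius)


def _conduction_paths(frame: _Frame, cfg: AnatomyConfig) -> dict[str, np.ndarray]:
    """Fascicle seed polylines on the septal endocardium (x = 0 plane).

    The proximal left bundle descends from the membranous high septum over
    about a quarter of the apicobasal length; the anterior, posterior, and
    septal fascicles fan out anterior-apically, inferior-apically, and
    mid-septally from its distal end.
    """
    L = cfg.long_axis_length

    def poly(wp, n=12):
        wp = np.asarray(wp, float)  # rows of (y_frac, z_frac)
        t = np.linspace(0, 1, n)
        yf = np.interp(t, np.linspace(0, 1, len(wp)), wp[:, 0])
        zf = np.interp(t, np.linspace(0, 1, len(wp)), wp[:, 1])
        pts = []
        for y_frac, z_frac in zip(yf, zf):
            pts.append(frame.septal_point(y_frac, z_frac * L))
        return np.asarray(pts)

    branch = (0.10, 0.72)
    return {
        "LBB": poly([(0.10, 0.95), branch]),
        "LAF": poly([branch, (0.30, 0.55), (0.45, 0.40)]),
        "LPF": poly([branch, (-0.30, 0.52), (-0.45, 0.35)]),
        "LSF": poly([branch, (0.02, 0.58), (0.0, 0.45)]),
    }


def generate_ed_scene(config: AnatomyConfig) -> EDScene:
    """Build the end-diastolic labeled scene.

    The cavity is sized analytically: transverse semi-axes are solved so the
    closed cavity mesh volume matches ``edv_target`` exactly (mesh volume
    scales linearly with the transverse cross-section area), well inside the
    2% design tolerance.
    """
    cfg = config
    # trial build to measure the template volume, then exact transverse rescale
    b0 = 50.0
    a0 = cfg.depth_ratio * b0
    v0 = closed_mesh_volume(_cavity_mesh(_Frame(a0, b0, cfg), cfg))
    s = math.sqrt(cfg.edv_target / v0)
    frame = _Frame(a0 * s, b0 * s, cfg)

    cavity = _cavity_mesh(frame, cfg)
    septum, septal_nodes, septal_faces = _septum_slab(frame, cfg)
    wall = _free_wall_shell(frame, cfg)
    ac, annulus_radius = _annulus_geometry(frame, cfg)
    L = cfg.long_axis_length

    # papillary muscles: tapered cones whose tips (basal-most points) are the
    # chordae tendineae attachment points
    pm_meshes, chordae = [], {}
    for spec in cfg.pm_specs:
        if spec.kind == "free_wall":
            attach = frame.free_wall_point(spec.angle_deg, spec.z_frac * L)
            inward = np.array([0.25 * frame.a, 0.0, 0.55 * L]) - attach
        else:
            attach = frame.septal_point(spec.y_frac, spec.z_frac * L)
            inward = np.array([1.0, 0.0, 0.0])
        direction = ac - attach
        direction = direction / np.linalg.norm(direction)
        tip = attach + spec.height * direction
        if not points_in_mesh(tip[None, :], cavity)[0]:
            raise ValueError(f"papillary muscle {spec.name!r} tip falls outside the cavity")
        pm_meshes.append(_cone(attach, direction, spec.base_radius, tip))
        chordae[spec.name] = tip
    if cfg.moderator_band is not None and pm_meshes:
        bs = cfg.moderator_band
        p0 = frame.septal_point(bs.septal_y_frac, bs.septal_z_frac * L)
        p1 = frame.free_wall_point(bs.wall_angle_deg, bs.wall_z_frac * L)
        pm_meshes.append(_capsule(p0, p1, bs.radius))

    # TV structures: the 2-mm annulus plane slab plus, when chordae exist,
    # the closed cone hull from the chordae points to the annulus ring
    ring = _circle(ac, np.array([0.0, 0.0, 1.0]), annulus_radius, n=24)
    slab = _hull_mesh(np.vstack([ring, ring + [0, 0, cfg.tv_plane_thickness]]))
    tv_parts = [slab]
    if chordae:
        tv_parts.insert(0, _hull_mesh(np.vstack([ring] + list(chordae.values()))))
    tv = _concat(tv_parts, CAT.TV)

    rx_b, ry_b = frame.radii(L)
    landmarks = {
        "apex": np.zeros(3),
        "tv_annulus_center": ac,
        "anterior_attachment": np.array([0.0, ry_b, L]),
        "posterior_attachment": np.array([0.0, -ry_b, L]),
    }
    structures = {CAT.SEPTUM: septum, CAT.RV_WALL: wall, CAT.TV: tv, CAT.CAVITY: cavity}
    if pm_meshes:
        structures[CAT.PM] = _concat(pm_meshes, CAT.PM)
    scene = LabeledScene(structures, landmarks)
    return EDScene(scene, chordae, _conduction_paths(frame, cfg), septal_nodes,
                   septal_faces, (frame.a, frame.b))


# ------------------------------------------------------------------------- motion


def _phase_weight(t: np.ndarray | float) -> np.ndarray | float:
    return (1.0 - np.cos(2.0 * np.pi * np.asarray(t, float))) / 2.0


def _solve_amplitude(ef_target: float, longitudinal_ratio: float) -> float:
    """Radial contraction amplitude A with (1-A)^2 (1-cA) = 1 - EF/100."""
    if ef_target == 0:
        return 0.0
    target = 1.0 - ef_target / 100.0
    g = lambda amp: (1 - amp) ** 2 * (1 - longitudinal_ratio * amp) - target
    if g(0.0) * g(0.999999) > 0:
        raise ValueError(f"ejection fraction {ef_target}% unreachable by this motion model")
    return float(brentq(g, 0.0, 0.999999, xtol=1e-12))


def generate_motion(ed: EDScene | LabeledScene, config: AnatomyConfig) -> SceneSequence:
    """Advect the end-diastolic scene through the cardiac cycle.

    The displacement field is an affine contraction about the apex/long
    axis: transverse scale ``1 - A w(t)``, longitudinal scale
    ``1 - cA w(t)`` with ``w(t) = (1 - cos 2 pi t)/2``, so cavity volume is
    ``EDV (1-Aw)^2 (1-cAw)`` exactly and the end-systolic frame (t = 0.5)
    hits the EF target to solver precision. All structures ride the same
    field; topology is constant.
    """
    scene = ed.scene if isinstance(ed, EDScene) else ed
    amp = _solve_amplitude(config.ef_target, config.longitudinal_ratio)
    frames = []
    for j in range(config.n_phases):
        w = _phase_weight(j / config.n_phases)
        sx = 1.0 - amp * w
        sz = 1.0 - config.longitudinal_ratio * amp * w
        scale = np.array([sx, sx, sz])
        structures = {
            cat: TriangleMesh(mesh.vertices * scale, mesh.faces.copy(), cat)
            for cat, mesh in scene.structures.items()
        }
        landmarks = {k: v * scale for k, v in scene.landmarks.items()}
        frames.append(LabeledScene(structures, landmarks))
    return SceneSequence(frames)


def measured_ef(sequence: SceneSequence) -> float:
    """Ejection fraction (%) from per-frame closed cavity volumes."""
    if CAT.CAVITY not in sequence.frames[0].structures:
        raise MeshValidationError("sequence has no CAVITY surface to measure")
    vols = np.array(
        [closed_mesh_volume(fr.structures[CAT.CAVITY]) for fr in sequence.frames]
    )
    return float(100.0 * (vols.max() - vols.min()) / vols.max())


def frame_volumes(sequence: SceneSequence) -> np.ndarray:
    """Per-frame cavity volume (mL)."""
    return np.array(
        [closed_mesh_volume(fr.structures[CAT.CAVITY]) for fr in sequence.frames]
    )


# -------------------------------------------------------------------------- cohort


@dataclass(frozen=True)
class CohortVariability:
    """Fractional/absolute spreads for the synthetic cohort.

    Defaults reproduce the calibration cohort's dispersion: EDV coefficient
    of variation 38/283, EF standard deviation 7 absolute %.
    """

    edv_frac: float = 38.0 / 283.0
    ef_sd: float = 7.0
    long_axis_frac: float = 0.05

    def zero(self) -> "CohortVariability":
        return CohortVariability(0.0, 0.0, 0.0)


def generate_patient(config: AnatomyConfig, patient_id: str = "p00") -> PatientAnatomy:
    ed = generate_ed_scene(config)
    seq = generate_motion(ed, config)
    return PatientAnatomy(
        patient_id=patient_id,
        config=config,
        sequence=seq,
        landmarks=ed.scene.landmarks,
        chordae_points=ed.chordae_points,
        conduction_paths=ed.conduction_paths,
        septal_node_ids=ed.septal_node_ids,
        septal_faces=ed.septal_faces,
    )


def generate_cohort(
    n: int,
    base: AnatomyConfig | None = None,
    variability: CohortVariability | None = None,
    seed: int = 0,
) -> list[PatientAnatomy]:
    """Draw ``n`` patient anatomies around a base configuration.

    Size parameters get log-normal multiplicative jitter; EF gets additive
    normal jitter (clipped to a physiologic range). Deterministic under
    ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base = base or AnatomyConfig()
    var = variability if variability is not None else CohortVariability()
    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n):
        edv = base.edv_target * float(np.exp(rng.normal(0.0, var.edv_frac)))
        ef = float(np.clip(rng.normal(base.ef_target, var.ef_sd), 2.0, 70.0))
        lax = base.long_axis_length * float(np.exp(rng.normal(0.0, var.long_axis_frac)))
        cfg = replace(base, edv_target=edv, ef_target=ef, long_axis_length=lax,
                      seed=int(rng.integers(2**31)))
        patients.append(generate_patient(cfg, patient_id=f"p{i:02d}"))
    return patients
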