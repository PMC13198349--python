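"""Virtual implantation: place a device at every septal node and track it.

A cylinder is seated with its base on the endocardial septal surface,
oriented along the inward surface normal, and carried through every cardiac
phase by the mesh motion. Collision with each structure category is tested
per frame; a site is positive for a category if it collides in at least one
frame, and positive for combined risk if any category is positive.

Faces of the RV wall within ``exclusion_radius`` of the attachment point are
excluded from the wall's surface tests (the self-intersection rule), and the
septum itself is never a collision target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .devices import DeviceSpec
from .geometry import Cylinder, _overlap_batch
from .mesh_io import StructureCategory, TriangleMesh
from .synthetic_anatomy import PatientAnatomy

CAT = StructureCategory
#: collision target categories, in reporting order
TARGETS = (CAT.RV_WALL, CAT.PM, CAT.TV)


@dataclass
class EngineConfig:
    exclusion_radius: float = 10.0
    exclusion_metric: str = "euclidean"  # or "geodesic" (slow; small scenes)
    per_frame_normals: bool = True
    perturbation_angle: float = 0.0  # degrees
    perturbation_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exclusion_radius < 0 or self.perturbation_angle < 0:
            raise ValueError("exclusion_radius and perturbation_angle must be >= 0")
        if self.exclusion_metric not in ("euclidean", "geodesic"):
            raise ValueError("exclusion_metric must be 'euclidean' or 'geodesic'")


@dataclass
class ImplantSite:
    patient_id: str
    node_index: int
    position: np.ndarray  # at ED
    normal: np.ndarray  # inward, at ED


@dataclass
class SiteCollisionRecord:
    site: ImplantSite
    device: DeviceSpec
    frames_hit: dict[CAT, int] = field(default_factory=dict)  # bitmask, bit j = frame j

    @property
    def positive(self) -> dict[CAT, bool]:
        return {c: bool(m) for c, m in self.frames_hit.items()}

    @property
    def combined(self) -> bool:
        return any(self.frames_hit.values())


def site_normals(anatomy: PatientAnatomy, per_frame: bool = True) -> np.ndarray:
    """(n_frames, n_sites, 3) inward unit normals at the septal nodes.

    Area-weighted average of the incident endocardial-face normals,
    re-normalized and sign-flipped toward the cavity centroid of the frame.
    When ``per_frame`` is false the end-diastolic normals are repeated.
    """
    seq = anatomy.sequence
    faces = anatomy.septal_faces
    node_ids = anatomy.septal_node_ids
    counts = np.zeros(int(node_ids.max()) + 1)
    np.add.at(counts, faces.ravel(), 1.0)
    if (counts[node_ids] == 0).any():
        raise ValueError("isolated septal node: no incident endocardial faces")
    out = []
    frames = seq.frames if per_frame else [seq.frames[0]]
    for fr in frames:
        verts = fr.structures[CAT.SEPTUM].vertices
        t = verts[faces]
        fn = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        vn = np.zeros((len(verts), 3))
        for k in range(3):
            np.add.at(vn, faces[:, k], fn)
        vn = vn[node_ids]
        nrm = np.linalg.norm(vn, axis=1, keepdims=True)
        vn = vn / np.where(nrm > 1e-12, nrm, 1.0)
        centroid = fr.structures[CAT.CAVITY].vertices.mean(axis=0) if (
            CAT.CAVITY in fr.structures
        ) else np.concatenate(
            [m.vertices for m in fr.structures.values()]
        ).mean(axis=0)
        flip = np.einsum("ij,ij->i", vn, centroid - verts[node_ids]) < 0
        vn[flip] *= -1.0
        out.append(vn)
    arr = np.stack(out)
    if not per_frame:
        arr = np.repeat(arr, seq.n_phases, axis=0)
    return arr


def _site_bases(anatomy: PatientAnatomy) -> np.ndarray:
    """(n_frames, n_sites, 3) tracked node positions."""
    verts = anatomy.sequence.category_vertices(CAT.SEPTUM)
    return verts[:, anatomy.septal_node_ids]


def place_and_track(
    site: ImplantSite,
    device: DeviceSpec,
    anatomy: PatientAnatomy,
    config: EngineConfig | None = None,
) -> list[Cylinder]:
    """The device cylinder at every frame, riding the septal node."""
    config = config or EngineConfig()
    bases = _site_bases(anatomy)
    normals = site_normals(anatomy, per_frame=config.per_frame_normals)
    idx = int(np.flatnonzero(anatomy.septal_node_ids == site.node_index)[0])
    return [
        Cylinder(bases[j, idx], normals[j, idx], device.length, device.radius)
        for j in range(anatomy.sequence.n_phases)
    ]


def _geodesic_face_exclusion(mesh: TriangleMesh, base: np.ndarray,
                             radius: float) -> np.ndarray:
    """Faces whose centroid geodesic distance (along mesh edges from the
    vertex nearest the base) is below ``radius``."""
    v = mesh.vertices
    e = np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]],
                        mesh.faces[:, [2, 0]]])
    w = np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)
    g = coo_matrix((w, (e[:, 0], e[:, 1])), shape=(len(v), len(v)))
    src = int(np.argmin(np.linalg.norm(v - base, axis=1)))
    d = dijkstra(g, directed=False, indices=src)
    entry = np.linalg.norm(v[src] - base)
    dist_f = (d[mesh.faces].mean(axis=1)) + entry
    return dist_f < radius


def _assess_batch(
    anatomy: PatientAnatomy,
    device: DeviceSpec,
    config: EngineConfig,
    axes_override: np.ndarray | None = None,
) -> dict[CAT, np.ndarray]:
    """(n_sites, n_frames) per-category hit matrix for all septal nodes."""
    seq = anatomy.sequence
    bases = _site_bases(anatomy)
    axes = axes_override if axes_override is not None else site_normals(
        anatomy, per_frame=config.per_frame_normals
    )
    n_sites = bases.shape[1]
    hits: dict[CAT, np.ndarray] = {}
    for cat in TARGETS:
        if cat not in seq.frames[0].structures:
            continue
        mat = np.zeros((n_sites, seq.n_phases), dtype=bool)
        for j, fr in enumerate(seq.frames):
            mesh = fr.structures[cat]
            excl_r = config.exclusion_radius if cat == CAT.RV_WALL else 0.0
            if excl_r and config.exclusion_metric == "geodesic":
                # per-site geodesic masks: fall back to per-site evaluation
                for i in range(n_sites):
                    mask = _geodesic_face_exclusion(mesh, bases[j, i], excl_r)
                    hit, _ = _overlap_batch(
                        bases[j, i][None], axes[j, i][None], device.length,
                        device.radius, mesh, static_excluded_faces=mask,
                    )
                    mat[i, j] = hit[0]
            else:
                hit, _ = _overlap_batch(
                    bases[j], axes[j], device.length, device.radius, mesh,
                    exclusion_radius=excl_r,
                )
                mat[:, j] = hit
        hits[cat] = mat
    return hits


def assess_site(
    site: ImplantSite,
    device: DeviceSpec,
    anatomy: PatientAnatomy,
    config: EngineConfig | None = None,
) -> SiteCollisionRecord:
    """Per-structure, per-frame collision outcome for one septal node."""
    config = config or EngineConfig()
    recs = run_patient(anatomy, device, config)
    for r in recs:
        if r.site.node_index == site.node_index:
            return r
    raise ValueError(f"node {site.node_index} is not a septal implant node")


def run_patient(
    anatomy: PatientAnatomy,
    device: DeviceSpec,
    config: EngineConfig | None = None,
) -> list[SiteCollisionRecord]:
    """One collision record per septal node, sorted by node index."""
    config = config or EngineConfig()
    hits = _assess_batch(anatomy, device, config)
    bases = _site_bases(anatomy)
    normals = site_normals(anatomy, per_frame=config.per_frame_normals)
    records = []
    order = np.argsort(anatomy.septal_node_ids)
    for i in order:
        node = int(anatomy.septal_node_ids[i])
        site = ImplantSite(anatomy.patient_id, node, bases[0, i].copy(),
                           normals[0, i].copy())
        masks = {
            cat: int(sum(1 << j for j in np.flatnonzero(hits[cat][i])))
            if cat in hits else 0
            for cat in TARGETS
        }
        records.append(SiteCollisionRecord(site, device, masks))
    return records


def orientation_sensitivity(
    anatomy: PatientAnatomy,
    device: DeviceSpec,
    config: EngineConfig,
) -> np.ndarray:
    """Per-site combined-risk proportion under randomly tilted axes.

    Each sample tilts every site's axis by an angle drawn uniformly in
    [0, perturbation_angle] degrees about a uniformly random azimuth.
    Deterministic under ``config.seed``; with a zero angle this reproduces
    the unperturbed assessment exactly.
    """
    if config.perturbation_samples < 1:
        raise ValueError("perturbation_samples must be >= 1")
    rng = np.random.default_rng(config.seed)
    base_axes = site_normals(anatomy, per_frame=config.per_frame_normals)
    n_frames, n_sites, _ = base_axes.shape
    pos = np.zeros(n_sites)
    for _ in range(config.perturbation_samples):
        theta = np.radians(rng.uniform(0.0, config.perturbation_angle, n_sites))
        phi = rng.uniform(0.0, 2 * np.pi, n_sites)
        axes = np.empty_like(base_axes)
        for j in range(n_frames):
            a = base_axes[j]
            ref = np.where(np.abs(a[:, [0]]) < 0.9, [[1.0, 0, 0]], [[0.0, 1, 0]])
            u = np.cross(a, ref)
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            v = np.cross(a, u)
            axes[j] = (
                np.cos(theta)[:, None] * a
                + (np.sin(theta) * np.cos(phi))[:, None] * u
                + (np.sin(theta) * np.sin(phi))[:, None] * v
            )
        hits = _assess_batch(anatomy, device, config, axes_override=axes)
        combined = np.zeros(n_sites, dtype=bool)
        for mat in hits.values():
            combined |= mat.any(axis=1)
        pos += combined
    return pos / config.perturbation_samples


def records_to_frame(records: list[SiteCollisionRecord]) -> pd.DataFrame:
    """Flatten collision records into the CSV schema."""
    rows = []
    for r in records:
        row = {
            "patient": r.site.patient_id,
            "node": r.site.node_index,
            "device": r.device.name,
            "length_mm": r.device.length,
            "diameter_mm": r.device.diameter,
            "rv_wall": r.positive.get(CAT.RV_WALL, False),
            "pm": r.positive.get(CAT.PM, False),
            "tv": r.positive.get(CAT.TV, False),
            "combined": r.combined,
        }
        for cat in TARGETS:
            row[f"frames_hit_{cat.value.lower()}"] = r.frames_hit.get(cat, 0)
        rows.append(row)
    return pd.DataFrame(rows)
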