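"""Labeled triangle meshes, time sequences, and standard-format I/O.

All coordinates are millimetres; volumes are reported in mL (= cm^3).
Meshes are plain vertex/face arrays with 0-based indexing; formats with
1-based indices (OBJ) are converted at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import trimesh


class StructureCategory(str, Enum):
    """Structure categories carried by a labeled scene.

    SEPTUM and RV_WALL are mandatory. PM bundles the papillary muscles and
    the moderator band; TV bundles the tricuspid-valve apparatus (annulus
    slab, leaflets/chordae cone). CAVITY is the closed RV blood-pool surface
    used for volume and ejection-fraction measurements; it is never a
    collision target.
    """

    SEPTUM = "SEPTUM"
    RV_WALL = "RV_WALL"
    PM = "PM"
    TV = "TV"
    CAVITY = "CAVITY"


_REQUIRED = (StructureCategory.SEPTUM, StructureCategory.RV_WALL)


class MeshValidationError(ValueError):
    """Raised when a mesh or scene violates a structural invariant."""


@dataclass
class TriangleMesh:
    """A triangle surface mesh in mm with a structure label."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int, 0-based
    label: StructureCategory | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshValidationError("face indices out of range")

    # -- basic derived quantities -------------------------------------------------

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.face_areas().sum())

    def drop_degenerate(self, tol: float = 1e-12) -> "TriangleMesh":
        """Return a copy with zero-area faces removed."""
        keep = self.face_areas() > tol
        return TriangleMesh(self.vertices.copy(), self.faces[keep], self.label)

    def boundary_edge_count(self) -> int:
        """Number of edges not shared by exactly two faces."""
        if not len(self.faces):
            return 0
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return int((counts != 2).sum())

    def is_closed(self) -> bool:
        return self.boundary_edge_count() == 0

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        """Apply a rigid transform x -> R x + t."""
        r = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return TriangleMesh(self.vertices @ r.T + t, self.faces.copy(), self.label)


def closed_mesh_volume(mesh: TriangleMesh) -> float:
    """Volume enclosed by a closed, consistently oriented surface, in mL.

    Uses the divergence theorem (sum of signed tetrahedron volumes against
    the origin); the absolute value is returned so either orientation works.
    Raises :class:`MeshValidationError` on an open mesh, naming the number
    of boundary edges.
    """
    nb = mesh.boundary_edge_count()
    if nb:
        raise MeshValidationError(
            f"mesh is not closed: {nb} boundary/non-manifold edges"
        )
    t = mesh.triangles
    signed = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])) / 6.0
    return abs(float(signed.sum())) / 1000.0


@dataclass
class LabeledScene:
    """One cardiac phase: a mesh per structure category plus landmarks."""

    structures: dict[StructureCategory, TriangleMesh]
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.structures = {StructureCategory(k): v for k, v in self.structures.items()}
        for cat in _REQUIRED:
            if cat not in self.structures:
                raise MeshValidationError(f"scene is missing required category {cat.value}")
        self.landmarks = {k: np.asarray(v, float) for k, v in self.landmarks.items()}

    def categories(self) -> list[StructureCategory]:
        return list(self.structures)


@dataclass
class SceneSequence:
    """An ordered sequence of scenes over the cardiac cycle.

    Topology (per-category vertex count and face connectivity) must be
    identical in every frame: the motion is a vertex displacement field.
    """

    frames: list[LabeledScene]

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise MeshValidationError("a scene sequence needs at least 2 frames")
        ref = self.frames[0]
        for i, fr in enumerate(self.frames[1:], start=1):
            if set(fr.structures) != set(ref.structures):
                raise MeshValidationError(f"frame {i}: category set differs from frame 0")
            for cat, mesh in fr.structures.items():
                m0 = ref.structures[cat]
                if len(mesh.vertices) != len(m0.vertices) or not np.array_equal(
                    mesh.faces, m0.faces
                ):
                    raise MeshValidationError(
                        f"frame {i}, {cat.value}: topology differs from frame 0"
                    )

    @property
    def n_phases(self) -> int:
        return len(self.frames)

    @property
    def phase_fractions(self) -> np.ndarray:
        return np.arange(self.n_phases) / self.n_phases

    def category_vertices(self, cat: StructureCategory) -> np.ndarray:
        """(n_phases, n_vertices, 3) stacked vertex trajectories."""
        return np.stack([fr.structures[cat].vertices for fr in self.frames])


# ----------------------------------------------------------------------------- I/O


def _write_vtk_polydata(path: Path, mesh: TriangleMesh) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{(mesh.label.value if mesh.label else 'mesh')}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        np.savetxt(fh, mesh.vertices, fmt="%.17g")
        m = len(mesh.faces)
        fh.write(f"POLYGONS {m} {4 * m}\n")
        np.savetxt(
            fh,
            np.column_stack([np.full(m, 3, dtype=np.int64), mesh.faces]),
            fmt="%d",
        )


def _read_vtk_polydata(path: Path) -> TriangleMesh:
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise MeshValidationError(f"{path}: not a VTK legacy file")
    if lines[2].strip().upper() != "ASCII":
        raise MeshValidationError(f"{path}: only ASCII VTK legacy files are supported")
    for ln in lines[3:]:
        tokens.extend(ln.split())
    i = 0

    def expect(word: str) -> None:
        nonlocal i
        while i < len(tokens) and tokens[i].upper() != word:
            i += 1
        if i == len(tokens):
            raise MeshValidationError(f"{path}: missing {word} section")
        i += 1

    expect("POINTS")
    n = int(tokens[i]); i += 2  # skip dtype
    pts = np.array(tokens[i : i + 3 * n], dtype=float).reshape(n, 3)
    i += 3 * n
    expect("POLYGONS")
    m = int(tokens[i]); size = int(tokens[i + 1]); i += 2
    flat = np.array(tokens[i : i + size], dtype=np.int64)
    faces = []
    j = 0
    for _ in range(m):
        k = int(flat[j])
        poly = flat[j + 1 : j + 1 + k]
        for a in range(1, k - 1):  # fan-triangulate
            faces.append((poly[0], poly[a], poly[a + 1]))
        j += k + 1
    return TriangleMesh(pts, np.array(faces, dtype=np.int64).reshape(-1, 3))


def _write_ply(path: Path, mesh: TriangleMesh) -> None:
    """Binary little-endian PLY with double-precision coordinates.

    Written directly (rather than through a mesh library) so that vertex
    order and full float64 precision survive the round trip.
    """
    n, m = len(mesh.vertices), len(mesh.faces)
    header = (
        "ply\nformat binary_little_endian 1.0\n"
        f"element vertex {n}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {m}\n"
        "property list uchar int32 vertex_indices\nend_header\n"
    )
    face_rec = np.empty(m, dtype=[("k", "u1"), ("idx", "<i4", (3,))])
    face_rec["k"] = 3
    face_rec["idx"] = mesh.faces
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes())
        fh.write(face_rec.tobytes())


_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "short": "i2", "ushort": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "double": "f8", "float32": "f4", "float64": "f8",
}


def _read_ply(path: Path) -> TriangleMesh:
    with open(path, "rb") as fh:
        raw = fh.read()
    end = raw.find(b"end_header\n")
    if not raw.startswith(b"ply") or end < 0:
        raise MeshValidationError(f"{path}: not a PLY file")
    header = raw[:end].decode("ascii", "replace").splitlines()
    body = raw[end + len(b"end_header\n"):]
    fmt = next((l.split()[1] for l in header if l.startswith("format")), "")
    elements: list[tuple[str, int, list]] = []
    for line in header:
        parts = line.split()
        if parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property" and elements:
            elements[-1][2].append(parts[1:])
    verts = faces = None
    if fmt == "ascii":
        tokens = body.split()
        pos = 0
        for name, count, props in elements:
            if name == "vertex":
                width = len(props)
                arr = np.array(tokens[pos: pos + count * width], dtype=float)
                verts = arr.reshape(count, width)[:, :3]
                pos += count * width
            elif name == "face":
                rows = []
                for _ in range(count):
                    k = int(tokens[pos]); pos += 1
                    rows.append([int(t) for t in tokens[pos: pos + k]])
                    pos += k
                faces = rows
    elif fmt == "binary_little_endian":
        off = 0
        for name, count, props in elements:
            if name == "vertex":
                dt = np.dtype([(p[1], "<" + _PLY_TYPES[p[0]]) for p in props])
                arr = np.frombuffer(body, dtype=dt, count=count, offset=off)
                verts = np.column_stack([arr["x"], arr["y"], arr["z"]]).astype(float)
                off += dt.itemsize * count
            elif name == "face":
                cnt_t = "<" + _PLY_TYPES[props[0][1]]
                idx_t = "<" + _PLY_TYPES[props[0][2]]
                rows = []
                for _ in range(count):
                    k = int(np.frombuffer(body, cnt_t, 1, off)[0])
                    off += np.dtype(cnt_t).itemsize
                    rows.append(np.frombuffer(body, idx_t, k, off).tolist())
                    off += np.dtype(idx_t).itemsize * k
                faces = rows
    else:
        raise MeshValidationError(f"{path}: unsupported PLY format {fmt!r}")
    if verts is None or faces is None:
        raise MeshValidationError(f"{path}: missing vertex or face element")
    tri = []
    for poly in faces:
        for a in range(1, len(poly) - 1):  # fan-triangulate
            tri.append((poly[0], poly[a], poly[a + 1]))
    return TriangleMesh(verts, np.asarray(tri, dtype=np.int64).reshape(-1, 3))


_FORMATS = ("vtk", "ply", "obj")


def write_mesh(path: str | Path, mesh: TriangleMesh, fmt: str | None = None) -> None:
    """Write a mesh as VTK legacy polydata (ASCII), PLY, or OBJ."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "vtk":
        _write_vtk_polydata(path, mesh)
    elif fmt == "ply":
        _write_ply(path, mesh)
    elif fmt == "obj":
        # trimesh handles the 1-based OBJ convention internally.
        mesh.as_trimesh().export(path, file_type=fmt)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r} (use one of {_FORMATS})")


def read_mesh(path: str | Path, fmt: str | None = None,
              label: StructureCategory | None = None) -> TriangleMesh:
    """Read a mesh; unreadable files raise :class:`MeshValidationError`."""
    path = Path(path)
    if not path.exists():
        raise MeshValidationError(f"mesh file not found: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "vtk":
        out = _read_vtk_polydata(path)
    elif fmt == "ply":
        out = _read_ply(path)
    elif fmt == "obj":
        tm = trimesh.load(path, file_type=fmt, process=False, force="mesh")
        out = TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces))
    else:
        raise ValueError(f"unsupported mesh format {fmt!r} (use one of {_FORMATS})")
    out.label = label
    return out


def write_scene_sequence(directory: str | Path, seq: SceneSequence,
                         fmt: str = "vtk") -> Path:
    """Write one file per frame per category plus a JSON manifest.

    Files follow the ``{category}_{frame:02d}.{fmt}`` pattern; the manifest
    records the layout, the landmarks, and the frame count, and is the
    single entry point for :func:`read_scene_sequence`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"n_phases": seq.n_phases, "format": fmt, "files": {}}
    for cat in seq.frames[0].categories():
        manifest["files"][cat.value] = []
        for j, fr in enumerate(seq.frames):
            name = f"{cat.value.lower()}_{j:02d}.{fmt}"
            write_mesh(directory / name, fr.structures[cat], fmt)
            manifest["files"][cat.value].append(name)
    manifest["landmarks"] = {
        k: list(map(float, v)) for k, v in seq.frames[0].landmarks.items()
    }
    mpath = directory / "scene_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_scene_sequence(
    paths: str | Path | Mapping[str, Sequence[str | Path]],
    fmt: str | None = None,
    landmarks: Mapping[str, Sequence[float]] | None = None,
) -> SceneSequence:
    """Read a validated scene sequence.

    ``paths`` is either a manifest file (as written by
    :func:`write_scene_sequence`) or a mapping ``{category: [file per
    frame]}``. Raises on unknown category tags, unreadable files, or
    topology mismatches across frames.
    """
    base = Path(".")
    if isinstance(paths, (str, Path)):
        mpath = Path(paths)
        manifest = json.loads(mpath.read_text())
        base = mpath.parent
        fmt = fmt or manifest.get("format")
        landmarks = landmarks or manifest.get("landmarks", {})
        file_map = manifest["files"]
    else:
        file_map = paths
    cats: dict[StructureCategory, list[TriangleMesh]] = {}
    n_frames = None
    for key, files in file_map.items():
        try:
            cat = StructureCategory(key)
        except ValueError:
            raise MeshValidationError(f"unknown structure category tag {key!r}") from None
        if n_frames is None:
            n_frames = len(files)
        elif len(files) != n_frames:
            raise MeshValidationError(f"{key}: frame count differs across categories")
        cats[cat] = [read_mesh(base / f, fmt, label=cat) for f in files]
    if not cats or n_frames is None:
        raise MeshValidationError("empty scene sequence")
    lm = {k: np.asarray(v, float) for k, v in (landmarks or {}).items()}
    frames = [
        LabeledScene({c: meshes[j] for c, meshes in cats.items()}, dict(lm))
        for j in range(n_frames)
    ]
    return SceneSequence(frames)
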