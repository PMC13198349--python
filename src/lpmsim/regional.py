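"""Septal surface parameterization and region assignment.

Septal nodes get apicobasal/circumferential coordinates (rho, phi) in
[0, 1]^2 from the anatomical landmarks: rho is 0 at the apex and 1 on the
basal (tricuspid annulus) plane; phi is 0 on the anterior RV-attachment line
and 1 on the posterior/inferior one. On this chart the septal AHA segments
{2, 3, 8, 9, 14}, the left-bundle-branch pacing regions (LBB/LAF/LPF/LSF),
and the 20-mm tricuspid annulus band are assigned, and per-node fields are
resampled onto a standardized grid for cross-patient aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, MultiPoint

from .mesh_io import StructureCategory
from .synthetic_anatomy import PatientAnatomy

#: septal AHA segment ids: basal antero/inferoseptal, mid antero/inferoseptal, apical
AHA_SEGMENTS = (2, 3, 8, 9, 14)
LBBAP_BRANCHES = ("LBB", "LAF", "LPF", "LSF")

#: default width (mm) by which fascicle hulls are dilated on the chart
LBBAP_MARGIN_MM = 5.0

#: TV-band distance threshold (mm below the annulus plane)
TV_BAND_MM = 20.0


@dataclass
class SeptalCoordinates:
    node_ids: np.ndarray
    rho: np.ndarray  # apicobasal, 0 apex .. 1 base
    phi: np.ndarray  # 0 anterior attachment .. 1 posterior attachment


@dataclass
class RegionLabels:
    node_ids: np.ndarray
    aha: np.ndarray  # int, in AHA_SEGMENTS
    lbbap: np.ndarray  # str, branch name or "none"
    tv_band: np.ndarray  # bool


class _Chart:
    """Landmark frame shared by all coordinate computations."""

    def __init__(self, landmarks: dict[str, np.ndarray]):
        try:
            self.apex = np.asarray(landmarks["apex"], float)
            self.ac = np.asarray(landmarks["tv_annulus_center"], float)
            ant = np.asarray(landmarks["anterior_attachment"], float)
            post = np.asarray(landmarks["posterior_attachment"], float)
        except KeyError as e:  # pragma: no cover - defensive
            raise ValueError(f"missing landmark {e}") from None
        n = np.cross(ant - self.ac, post - self.ac)
        nn = np.linalg.norm(n)
        if nn < 1e-9 or np.linalg.norm(self.ac - self.apex) < 1e-9:
            raise ValueError("degenerate landmarks: basal plane undefined")
        n /= nn
        if np.dot(self.apex - self.ac, n) > 0:
            n = -n  # apex on the negative side
        self.plane_normal = n
        self.apex_depth = -float(np.dot(self.apex - self.ac, n))  # > 0
        axis = self.ac - self.apex
        self.axis = axis / np.linalg.norm(axis)
        self.e_ant = self._perp(ant - self.apex)
        self.e_post = self._perp(post - self.apex)
        self.total_angle = self._signed_angle(self.e_ant, self.e_post)
        if abs(self.total_angle) < 1e-9:
            raise ValueError("degenerate landmarks: attachment lines coincide")
        self.septal_width = float(np.linalg.norm(ant - post))

    def _perp(self, v: np.ndarray) -> np.ndarray:
        return v - np.outer(v @ self.axis, self.axis) if v.ndim == 2 else (
            v - (v @ self.axis) * self.axis
        )

    def _signed_angle(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        cross = np.cross(a, b)
        s = cross @ self.axis
        c = np.einsum("...i,...i->...", a, b)
        return np.arctan2(s, c)

    def coords(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = np.atleast_2d(np.asarray(points, float))
        s = (p - self.ac) @ self.plane_normal  # signed plane distance, apex < 0
        rho = np.clip(1.0 - (-s) / self.apex_depth, 0.0, 1.0)
        u = self._perp(p - self.apex)
        ang = self._signed_angle(np.broadcast_to(self.e_ant, u.shape), u)
        phi = np.clip(ang / self.total_angle, 0.0, 1.0)
        return rho, phi

    def plane_distance_below(self, points: np.ndarray) -> np.ndarray:
        """Distance (mm) below the annulus plane; 0 on or above the plane."""
        p = np.atleast_2d(np.asarray(points, float))
        return np.maximum(0.0, -((p - self.ac) @ self.plane_normal))


def _ed_positions(anatomy: PatientAnatomy) -> np.ndarray:
    septum = anatomy.sequence.frames[0].structures[StructureCategory.SEPTUM]
    return septum.vertices[anatomy.septal_node_ids]


def compute_coordinates(anatomy: PatientAnatomy,
                        landmarks: dict[str, np.ndarray] | None = None) -> SeptalCoordinates:
    """(rho, phi) for every septal implant node, from the ED landmarks."""
    chart = _Chart(landmarks or anatomy.landmarks)
    rho, phi = chart.coords(_ed_positions(anatomy))
    return SeptalCoordinates(anatomy.septal_node_ids.copy(), rho, phi)


def assign_aha(coords: SeptalCoordinates) -> np.ndarray:
    """AHA septal segment per node.

    Basal third: 2 (anteroseptal, phi < 0.5) / 3 (inferoseptal); mid third:
    8 / 9 by the same split; apical third: 14. Every node gets exactly one
    label.
    """
    rho, phi = coords.rho, coords.phi
    aha = np.full(len(rho), 14, dtype=int)
    basal = rho >= 2.0 / 3.0
    mid = (rho >= 1.0 / 3.0) & ~basal
    anterior = phi < 0.5
    aha[basal & anterior] = 2
    aha[basal & ~anterior] = 3
    aha[mid & anterior] = 8
    aha[mid & ~anterior] = 9
    return aha


def tv_band(anatomy: PatientAnatomy, threshold_mm: float = TV_BAND_MM) -> np.ndarray:
    """True for nodes within ``threshold_mm`` of the TV annulus plane slab (ED)."""
    chart = _Chart(anatomy.landmarks)
    return chart.plane_distance_below(_ed_positions(anatomy)) < threshold_mm


def lbbap_regions(
    anatomy: PatientAnatomy,
    coords: SeptalCoordinates | None = None,
    margin_mm: float = LBBAP_MARGIN_MM,
) -> np.ndarray:
    """Pacing-region label (branch name or "none") per septal node.

    Each branch region is the 2D convex hull of the branch polyline on the
    (rho, phi) chart, dilated by ``margin_mm`` (converted to chart units via
    the patient's apicobasal depth and septal width); a degenerate
    (collinear) hull falls back to a buffered polyline corridor, which is
    what ``shapely`` buffering produces naturally. Nodes inside several
    hulls go to the branch with the nearest path centroid.
    """
    coords = coords or compute_coordinates(anatomy)
    chart = _Chart(anatomy.landmarks)
    sx, sy = chart.apex_depth, chart.septal_width  # chart -> mm scales

    node_xy = np.column_stack([coords.rho * sx, coords.phi * sy])
    labels = np.full(len(node_xy), "none", dtype=object)
    dist_to_centroid = np.full(len(node_xy), np.inf)
    for name in LBBAP_BRANCHES:
        path = anatomy.conduction_paths.get(name)
        if path is None:
            continue
        rho_p, phi_p = chart.coords(path)
        pts = np.column_stack([rho_p * sx, phi_p * sy])
        geom = MultiPoint(list(map(tuple, pts))).convex_hull
        if geom.geom_type != "Polygon":  # collinear path: corridor fallback
            geom = LineString(pts).buffer(margin_mm)
        else:
            geom = geom.buffer(margin_mm)
        inside = shapely.contains_xy(geom, node_xy[:, 0], node_xy[:, 1])
        centroid = pts.mean(axis=0)
        d = np.linalg.norm(node_xy - centroid, axis=1)
        take = inside & (d < dist_to_centroid)
        labels[take] = name
        dist_to_centroid[take] = d[take]
    return labels.astype(str)


def compute_region_labels(anatomy: PatientAnatomy) -> RegionLabels:
    coords = compute_coordinates(anatomy)
    return RegionLabels(
        node_ids=coords.node_ids,
        aha=assign_aha(coords),
        lbbap=lbbap_regions(anatomy, coords),
        tv_band=tv_band(anatomy),
    )


def grid_resample(
    coords: SeptalCoordinates,
    values: np.ndarray,
    resolution: tuple[int, int] = (50, 50),
    reduce: str = "mean",
) -> np.ma.MaskedArray:
    """Bin per-node values into a (rho x phi) grid; empty cells are masked.

    ``reduce`` is "mean" (cell average; fraction for booleans) or "any".
    """
    nr, np_ = resolution
    if nr < 2 or np_ < 2:
        raise ValueError("grid resolution must be at least 2x2")
    values = np.asarray(values, float)
    ir = np.clip((coords.rho * nr).astype(int), 0, nr - 1)
    ip = np.clip((coords.phi * np_).astype(int), 0, np_ - 1)
    flat = ir * np_ + ip
    count = np.bincount(flat, minlength=nr * np_).astype(float)
    if reduce == "mean":
        total = np.bincount(flat, weights=values, minlength=nr * np_)
        with np.errstate(invalid="ignore"):
            cell = total / count
    elif reduce == "any":
        cell = np.bincount(flat, weights=(values != 0), minlength=nr * np_) > 0
        cell = cell.astype(float)
    else:
        raise ValueError("reduce must be 'mean' or 'any'")
    grid = np.ma.masked_array(cell.reshape(nr, np_), mask=(count == 0).reshape(nr, np_))
    return grid
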