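"""Reproduction workflows: calibration checks and the default cohort study.

These functions recompute, from scratch, the quantities the package is
validated against: the clinical calibration table re-derived through mesh
volumes, the device-sweep diameter range, ejection-fraction calibration
recovery, analytic-predicate vs. Monte-Carlo-oracle agreement on randomized
scenes, and the directional cohort results (length trend, apical vs. basal
ordering, tricuspid-band contrast).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import trimesh

from .cohort import collision_free_fraction, length_trend, regional_stats, risks_to_frame
from .devices import catalogue, build_sweep, volume_preserving_diameter
from .geometry import (
    Cylinder,
    _closest_point_on_triangle,
    _segment_triangle_closest,
    cylinder_mesh_overlap,
    overlap_oracle,
    points_in_mesh,
)
from .implant import EngineConfig, records_to_frame, run_patient
from .mesh_io import LabeledScene, SceneSequence, StructureCategory, TriangleMesh, closed_mesh_volume
from .pipeline import _plane_patch, _slab_from_patch
from .reference_cohort import reference_cohort
from .regional import compute_region_labels
from .synthetic_anatomy import (
    AnatomyConfig,
    CohortVariability,
    generate_cohort,
    generate_patient,
    measured_ef,
)

CAT = StructureCategory


# ----------------------------------------------------------- calibration-table check


def _sphere_mesh(volume_ml: float, subdivisions: int = 3) -> TriangleMesh:
    """Icosphere rescaled so its *mesh* volume equals ``volume_ml`` exactly."""
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=10.0)
    m0 = TriangleMesh(np.asarray(base.vertices, float), np.asarray(base.faces))
    scale = (volume_ml / closed_mesh_volume(m0)) ** (1.0 / 3.0)
    return TriangleMesh(m0.vertices * scale, m0.faces, CAT.CAVITY)


def volume_pair_sequence(edv_ml: float, esv_ml: float) -> SceneSequence:
    """Two-frame sequence of scaled spheres with the given cavity volumes."""
    dummy_v, dummy_f = _plane_patch(np.array([50.0, 0, 0]), [0, 5, 0], [0, 0, 5], 2, 2)
    septum = _slab_from_patch(dummy_v, dummy_f, np.array([-1.0, 0, 0]), CAT.SEPTUM)
    wall = _slab_from_patch(dummy_v + [5, 0, 0], dummy_f, np.array([1.0, 0, 0]),
                            CAT.RV_WALL)
    ed = _sphere_mesh(edv_ml)
    es = TriangleMesh(ed.vertices * (esv_ml / edv_ml) ** (1 / 3), ed.faces, CAT.CAVITY)
    frames = [
        LabeledScene({CAT.CAVITY: cav, CAT.SEPTUM: septum, CAT.RV_WALL: wall})
        for cav in (ed, es)
    ]
    return SceneSequence(frames)


def table1_statistics() -> dict[str, float]:
    """Cohort statistics recomputed through mesh volumes.

    Each patient's printed EDV/ESV become a two-frame scaled-sphere cavity
    sequence; EF is measured from the mesh volumes and summarized with the
    population (n) standard deviation.
    """
    table = reference_cohort()
    efs, edvs, esvs = [], [], []
    for _, row in table.iterrows():
        seq = volume_pair_sequence(row.rv_edv_ml, row.rv_esv_ml)
        vols = [closed_mesh_volume(fr.structures[CAT.CAVITY]) for fr in seq.frames]
        edvs.append(max(vols))
        esvs.append(min(vols))
        efs.append(measured_ef(seq))
    efs, edvs, esvs = map(np.asarray, (efs, edvs, esvs))
    age = table.age.to_numpy(float)
    return {
        "mean_age_y": float(age.mean()),
        "sd_age_y": float(age.std()),
        "mean_esv_ml": float(esvs.mean()),
        "mean_edv_ml": float(edvs.mean()),
        "sd_edv_ml": float(edvs.std()),
        "mean_rvef_pct": float(efs.mean()),
        "sd_rvef_pct": float(efs.std()),
        "per_patient_rvef_pct": [float(e) for e in efs],
        "n": int(len(table)),
    }


def sweep_diameter_range() -> tuple[float, float]:
    """Min/max diameters over the 15-45 mm sweep of the catalogue volumes."""
    from .devices import SWEEP_LENGTHS

    diams = [
        volume_preserving_diameter(dev.volume, l)
        for dev in catalogue()
        for l in SWEEP_LENGTHS
    ]
    return min(diams), max(diams)


# ------------------------------------------------------------- calibration recovery


def calibration_recovery(
    ef_targets: tuple[float, ...] = (10.0, 22.0, 40.0),
    edv_target: float = 283.0,
) -> dict[str, float]:
    """Generate anatomies at the given EF targets and re-measure EF and EDV."""
    ef_errors, edv_errors = [], []
    for ef in ef_targets:
        cfg = AnatomyConfig(edv_target=edv_target, ef_target=ef)
        pat = generate_patient(cfg)
        ef_errors.append(abs(measured_ef(pat.sequence) - ef))
        edv = closed_mesh_volume(pat.sequence.frames[0].structures[CAT.CAVITY])
        edv_errors.append(100.0 * abs(edv - edv_target) / edv_target)
    return {
        "max_ef_abs_error_pct": float(max(ef_errors)),
        "max_edv_rel_error_pct": float(max(edv_errors)),
        "ef_targets": list(ef_targets),
    }


# --------------------------------------------------- predicate vs. sampling oracle


def _random_convex_mesh(rng: np.random.Generator) -> TriangleMesh:
    kind = rng.integers(4)
    if kind == 0:
        tm = trimesh.creation.box(extents=rng.uniform(2, 12, 3))
    elif kind == 1:
        tm = trimesh.creation.icosphere(subdivisions=1, radius=rng.uniform(2, 8))
    elif kind == 2:
        tm = trimesh.creation.cylinder(radius=rng.uniform(1, 5),
                                       height=rng.uniform(2, 10), sections=12)
    else:
        tm = trimesh.convex.convex_hull(rng.uniform(-6, 6, (12, 3)))
    q = rng.normal(size=4)  # uniform-ish random rotation via quaternion
    q /= np.linalg.norm(q)
    r = trimesh.transformations.quaternion_matrix(q)
    r[:3, 3] = rng.uniform(-10, 10, 3)
    tm.apply_transform(r)
    return TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces))


def certify_scene(cyl: Cylinder, mesh: TriangleMesh,
                  gap_margin: float = 0.5, overlap_margin: float = 1.0) -> str | None:
    """Classify a scene as certified "gap"/"overlap", or None (sliver: skip).

    A gap certificate requires every face to clear the axis segment by more
    than ``radius + gap_margin`` with no containment either way. An overlap
    certificate requires a point that is at least ``overlap_margin`` interior
    to both solids, so the Monte-Carlo oracle resolves it. Scenes that admit
    neither certificate (grazing contacts, sliver overlaps) are ambiguous at
    sampling resolution and are excluded from oracle-equivalence runs.
    """
    tris = mesh.triangles
    k = len(tris)
    a0 = np.repeat(cyl.base[None, :], k, axis=0)
    a1 = np.repeat(cyl.tip[None, :], k, axis=0)
    d, _ = _segment_triangle_closest(a0, a1, tris)
    mid = cyl.base + 0.5 * cyl.length * cyl.axis
    mid_inside = bool(points_in_mesh(mid[None, :], mesh)[0])
    any_vert_in = bool(cyl.contains_points(mesh.vertices).any())
    if d.min() > cyl.radius + gap_margin and not mid_inside and not any_vert_in:
        return "gap"
    # overlap certificate: a deep-interior common point among axis samples
    ts = np.linspace(0.05, 0.95, 13)
    cands = cyl.base[None, :] + np.outer(ts * cyl.length, cyl.axis)
    ax = ts * cyl.length
    slack_cyl = np.minimum(np.minimum(ax, cyl.length - ax), cyl.radius)
    inside = points_in_mesh(cands, mesh)
    for q, s_c, ok in zip(cands, slack_cyl, inside):
        if not ok or s_c <= overlap_margin:
            continue
        dq = _closest_point_on_triangle(np.repeat(q[None, :], k, axis=0), tris)
        clearance = np.linalg.norm(dq - q, axis=1).min()
        if min(s_c, clearance) > overlap_margin:
            return "overlap"
    return None


def oracle_agreement(n_scenes: int = 1000, seed: int = 0,
                     n_samples: int = 4000) -> dict[str, float]:
    """Predicate vs. Monte-Carlo oracle over randomized certified scenes."""
    rng = np.random.default_rng(seed)
    done = disagreements = skipped = 0
    while done < n_scenes:
        mesh = _random_convex_mesh(rng)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        cyl = Cylinder(base=rng.uniform(-15, 15, 3), axis=axis,
                       length=rng.uniform(1, 20), radius=rng.uniform(0.3, 4))
        cert = certify_scene(cyl, mesh)
        if cert is None:
            skipped += 1
            continue
        pred = cylinder_mesh_overlap(cyl, mesh).collides
        orc = overlap_oracle(cyl, mesh, n_samples, seed=int(rng.integers(2**31)))
        disagreements += int(pred != orc)
        done += 1
    return {
        "n_scenes": done,
        "skipped_sliver_scenes": skipped,
        "disagreements": disagreements,
        "agreement_pct": 100.0 * (done - disagreements) / done,
    }


# ----------------------------------------------------------- default cohort study


def default_study(
    seed: int = 1,
    n_patients: int = 10,
    sweep_lengths: tuple[float, ...] = (25.0, 30.0, 35.0, 40.0, 45.0),
    anatomy: AnatomyConfig | None = None,
    engine: EngineConfig | None = None,
) -> dict:
    """Catalogue devices plus volume-preserving sweeps on the default cohort.

    Returns the flat site-record table together with the directional
    summaries: per-base-volume mean combined risk by length, the combined
    length-trend regression, AHA-region risks for the shortest catalogue
    device, and tricuspid-valve prevalence inside vs. outside the 20-mm
    annulus band.
    """
    anatomy = anatomy or AnatomyConfig()
    engine = engine or EngineConfig()
    cohort = generate_cohort(n_patients, anatomy, CohortVariability(), seed=seed)
    labels = {p.patient_id: compute_region_labels(p) for p in cohort}

    frames = []
    for base in catalogue():
        devs = list(build_sweep(base, sweep_lengths).derived) + [base]
        for dev in devs:
            for pat in cohort:
                frames.append(
                    records_to_frame(run_patient(pat, dev, engine)).assign(base=base.name)
                )
    records = pd.concat(frames, ignore_index=True)

    sweep_mask = records.device.str.contains("_L")
    sweep_means: dict[str, dict[float, float]] = {}
    for base_name, sub in records[sweep_mask].groupby("base"):
        sweep_means[base_name] = {
            float(l): float(g.groupby("patient").combined.mean().mean() * 100.0)
            for l, g in sub.groupby("length_mm")
        }

    trends = length_trend(records[sweep_mask & (records.base == "aveir_ar")], labels)
    combined_all = next(
        t for t in trends if t.region == "ALL_SEPTUM" and t.structure == "COMBINED"
    )

    micra = records[records.device == "micra_tps"]
    risks = risks_to_frame(regional_stats(micra, labels))
    combined = risks[risks.structure == "COMBINED"].set_index("region")

    lab = pd.concat([
        pd.DataFrame({"patient": p, "node": l.node_ids, "tv_band": l.tv_band})
        for p, l in labels.items()
    ])
    merged = records[~sweep_mask].merge(lab, on=["patient", "node"])
    tv_contrast = {
        dev: (float(100 * g[g.tv_band].tv.mean()), float(100 * g[~g.tv_band].tv.mean()))
        for dev, g in merged.groupby("device")
    }

    cf = {}
    for branch in ("LBB", "LAF", "LPF", "LSF"):
        try:
            cf[branch] = {
                "L25": collision_free_fraction(
                    records[records.device == "aveir_ar_L25"], labels, branch),
                "L40": collision_free_fraction(
                    records[records.device == "aveir_ar_L40"], labels, branch),
            }
        except (ValueError, KeyError):
            cf[branch] = None

    return {
        "records": records,
        "labels": labels,
        "cohort": cohort,
        "sweep_mean_combined": sweep_means,
        "trend_slope_per_5mm": combined_all.slope_per_5mm,
        "trend_pearson_r": combined_all.pearson_r,
        "micra_region_combined": {r: float(combined.loc[r, "mean"])
                                  for r in combined.index},
        "tv_in_out_band": tv_contrast,
        "collision_free_lbbap": cf,
    }
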