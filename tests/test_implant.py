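"""Implant engine: normals, tracking, per-site assessment, sensitivity."""

from dataclasses import replace

import numpy as np
import pytest
import trimesh

from lpmsim.devices import DeviceSpec, catalogue
from lpmsim.implant import (
    EngineConfig,
    ImplantSite,
    assess_site,
    orientation_sensitivity,
    place_and_track,
    records_to_frame,
    run_patient,
    site_normals,
)
from lpmsim.mesh_io import LabeledScene, SceneSequence, StructureCategory as C, TriangleMesh
from lpmsim.pipeline import box_anatomy
from lpmsim.synthetic_anatomy import AnatomyConfig, PatientAnatomy, generate_patient

from conftest import rigid_transform


def _sphere_anatomy(n_frames=2, transform_per_frame=None):
    """SEPTUM = icosphere (every node an implant site); CAVITY = same sphere."""
    tm = trimesh.creation.icosphere(subdivisions=2, radius=20.0)
    verts = np.asarray(tm.vertices, float)
    faces = np.asarray(tm.faces)
    frames = []
    for j in range(n_frames):
        v = verts if transform_per_frame is None else transform_per_frame(verts, j)
        structures = {
            C.SEPTUM: TriangleMesh(v.copy(), faces.copy(), C.SEPTUM),
            C.RV_WALL: TriangleMesh(v.copy() * 2.0, faces.copy(), C.RV_WALL),
            C.CAVITY: TriangleMesh(v.copy(), faces.copy(), C.CAVITY),
        }
        frames.append(LabeledScene(structures))
    return PatientAnatomy(
        patient_id="sphere", config=AnatomyConfig(),
        sequence=SceneSequence(frames), landmarks={}, chordae_points={},
        conduction_paths={}, septal_node_ids=np.arange(len(verts)),
        septal_faces=faces,
    )


class TestSiteNormals:
    def test_flat_septum_normals_point_into_cavity(self, micro_fixtures):
        anat = micro_fixtures["wall-hit"]["anatomy"]
        normals = site_normals(anat)
        np.testing.assert_allclose(normals, np.tile([1.0, 0, 0],
                                   normals.shape[:2] + (1,)), atol=1e-12)

    def test_sphere_normals_radial_inward(self):
        anat = _sphere_anatomy()
        normals = site_normals(anat)[0]
        verts = anat.sequence.frames[0].structures[C.SEPTUM].vertices
        radial = verts / np.linalg.norm(verts, axis=1, keepdims=True)
        # area-weighted discrete normals of an icosphere are radial up to
        # the faceting error of the tessellation
        dots = np.einsum("ij,ij->i", normals, -radial)
        assert dots.min() > 0.999

    def test_rigidly_rotated_sequence_rotates_normals(self):
        rot, _ = rigid_transform(2)
        anat = _sphere_anatomy(
            n_frames=2,
            transform_per_frame=lambda v, j: v @ rot.T if j else v,
        )
        normals = site_normals(anat, per_frame=True)
        np.testing.assert_allclose(normals[1], normals[0] @ rot.T, atol=1e-9)

    def test_ed_carried_normals(self):
        rot, _ = rigid_transform(3)
        anat = _sphere_anatomy(
            n_frames=2, transform_per_frame=lambda v, j: v @ rot.T if j else v)
        normals = site_normals(anat, per_frame=False)
        np.testing.assert_array_equal(normals[1], normals[0])


class TestPlaceAndTrack:
    def test_static_sequence_identical_cylinders(self, micro_fixtures):
        anat = micro_fixtures["wall-hit"]["anatomy"]
        node = int(anat.septal_node_ids[4])
        site = ImplantSite(anat.patient_id, node, np.zeros(3), np.array([1.0, 0, 0]))
        cyls = place_and_track(site, catalogue()[0], anat)
        for c in cyls[1:]:
            np.testing.assert_array_equal(c.base, cyls[0].base)
            np.testing.assert_array_equal(c.axis, cyls[0].axis)

    def test_pure_translation_moves_base_keeps_axis(self):
        shift = np.array([3.0, -2.0, 1.0])
        anat = _sphere_anatomy(
            n_frames=2, transform_per_frame=lambda v, j: v + j * shift)
        node = int(anat.septal_node_ids[10])
        site = ImplantSite("sphere", node, np.zeros(3), np.array([1.0, 0, 0]))
        cyls = place_and_track(site, catalogue()[0], anat)
        np.testing.assert_allclose(cyls[1].base, cyls[0].base + shift, atol=1e-12)
        np.testing.assert_allclose(cyls[1].axis, cyls[0].axis, atol=1e-12)

    def test_contraction_base_tracks_mesh_vertices(self, default_patient):
        node = int(default_patient.septal_node_ids[40])
        site = ImplantSite(default_patient.patient_id, node, np.zeros(3),
                           np.array([1.0, 0, 0]))
        cyls = place_and_track(site, catalogue()[0], default_patient)
        for j, cyl in enumerate(cyls):
            v = default_patient.sequence.frames[j].structures[C.SEPTUM].vertices[node]
            np.testing.assert_array_equal(cyl.base, v)


class TestAssessment:
    def test_wall_hit_fixture_exactly_one_site(self, micro_fixtures):
        fx = micro_fixtures["wall-hit"]
        df = records_to_frame(run_patient(fx["anatomy"], DeviceSpec("d", 25.0, 6.0)))
        assert int(df.rv_wall.sum()) == fx["colliding_nodes"]
        assert int(df.combined.sum()) == fx["colliding_nodes"]

    def test_wall_hit_needs_reach(self, micro_fixtures):
        fx = micro_fixtures["wall-hit"]
        df = records_to_frame(run_patient(fx["anatomy"],
                                          DeviceSpec("short", 15.0, 6.0)))
        assert int(df.combined.sum()) == 0

    def test_tv_graze_length_threshold(self, micro_fixtures):
        fx = micro_fixtures["tv-graze"]
        thr = fx["tv_threshold"]
        below = records_to_frame(run_patient(fx["anatomy"],
                                             DeviceSpec("b", thr - 0.5, 6.0)))
        above = records_to_frame(run_patient(fx["anatomy"],
                                             DeviceSpec("a", thr + 0.5, 6.0)))
        assert not below.tv.any()
        assert above.tv.all()

    def test_assess_site_matches_run_patient(self, micro_fixtures):
        anat = micro_fixtures["wall-hit"]["anatomy"]
        dev = DeviceSpec("d", 25.0, 6.0)
        recs = run_patient(anat, dev)
        center = recs[4]
        again = assess_site(center.site, dev, anat)
        assert again.frames_hit == center.frames_hit

    def test_structures_removed_only_wall_hits(self, coarse_config):
        cfg = replace(coarse_config, pm_specs=(), moderator_band=None)
        pat = generate_patient(cfg)
        df = records_to_frame(run_patient(pat, catalogue()[2]))
        assert not df.pm.any()
        assert (df.combined == (df.rv_wall | df.tv)).all()

    def test_two_runs_identical(self, micro_fixtures):
        anat = micro_fixtures["tv-graze"]["anatomy"]
        dev = DeviceSpec("d", 20.0, 5.0)
        a = records_to_frame(run_patient(anat, dev))
        b = records_to_frame(run_patient(anat, dev))
        assert a.equals(b)

    def test_combined_monotone_in_length_at_fixed_radius(self, coarse_config):
        pat = generate_patient(coarse_config)
        prev = None
        for L in (15.0, 25.0, 35.0, 45.0):
            df = records_to_frame(run_patient(pat, DeviceSpec(f"L{L}", L, 6.5)))
            cur = df.sort_values("node").combined.to_numpy()
            if prev is not None:
                assert not np.any(prev & ~cur), "a longer device lost a collision"
            prev = cur

    def test_removing_category_never_increases_prevalence(self, coarse_config):
        pat_full = generate_patient(coarse_config)
        cfg = replace(coarse_config, pm_specs=(), moderator_band=None)
        pat_no_pm = generate_patient(cfg)
        dev = catalogue()[1]
        full = records_to_frame(run_patient(pat_full, dev)).combined.mean()
        reduced = records_to_frame(run_patient(pat_no_pm, dev)).combined.mean()
        assert reduced <= full + 1e-12

    def test_exclusion_radius_suppresses_attachment_contact(self):
        """Wall faces within the exclusion radius of the base are not surface
        targets; with the exclusion disabled they are."""
        anat = box_anatomy(depth=5.0, extent=40.0, n_grid=3, wall_size=6.0)
        dev = DeviceSpec("d", 25.0, 6.0)  # pierces straight through the slab
        with_excl = records_to_frame(run_patient(anat, dev, EngineConfig()))
        without = records_to_frame(
            run_patient(anat, dev, EngineConfig(exclusion_radius=0.0)))
        assert not with_excl.rv_wall.any()
        assert int(without.rv_wall.sum()) == 1

    def test_exclusion_never_adds_hits(self, coarse_config):
        pat = generate_patient(coarse_config)
        dev = catalogue()[0]
        with_excl = records_to_frame(run_patient(pat, dev, EngineConfig()))
        without = records_to_frame(
            run_patient(pat, dev, EngineConfig(exclusion_radius=0.0)))
        merged = with_excl.sort_values("node").rv_wall.to_numpy()
        base = without.sort_values("node").rv_wall.to_numpy()
        assert not np.any(merged & ~base)

    def test_geodesic_exclusion_on_fixture(self, micro_fixtures):
        anat = micro_fixtures["wall-hit"]["anatomy"]
        dev = DeviceSpec("d", 25.0, 6.0)
        eu = records_to_frame(run_patient(anat, dev, EngineConfig()))
        ge = records_to_frame(run_patient(
            anat, dev, EngineConfig(exclusion_metric="geodesic")))
        # wall is 20 mm away from every septal node: exclusion is moot either way
        assert eu.rv_wall.equals(ge.rv_wall)


class TestOrientationSensitivity:
    def test_zero_angle_reproduces_assessment(self, micro_fixtures):
        anat = micro_fixtures["wall-hit"]["anatomy"]
        dev = DeviceSpec("d", 25.0, 6.0)
        cfg = EngineConfig(perturbation_angle=0.0, perturbation_samples=3, seed=9)
        risk = orientation_sensitivity(anat, dev, cfg)
        df = records_to_frame(run_patient(anat, dev))
        np.testing.assert_array_equal(risk, df.sort_values("node").combined.to_numpy())

    def test_marginal_geometry_risk_below_one(self, micro_fixtures):
        """A barely-reaching device misses under some tilts."""
        fx = micro_fixtures["wall-hit"]
        # thin device: tilting shortens its reach (L cos t + r sin t < wall)
        dev = DeviceSpec("d", fx["wall_distance"] + 0.05, 1.0)
        cfg = EngineConfig(perturbation_angle=8.0, perturbation_samples=16, seed=2)
        risk = orientation_sensitivity(fx["anatomy"], dev, cfg)
        center = 4  # the only colliding site
        assert 0.0 < risk[center] < 1.0

    def test_deterministic_under_seed(self, micro_fixtures):
        anat = micro_fixtures["tv-graze"]["anatomy"]
        dev = DeviceSpec("d", 15.5, 6.0)
        cfg = EngineConfig(perturbation_angle=5.0, perturbation_samples=4, seed=33)
        a = orientation_sensitivity(anat, dev, cfg)
        b = orientation_sensitivity(anat, dev, cfg)
        np.testing.assert_array_equal(a, b)

    def test_invalid_samples(self, micro_fixtures):
        with pytest.raises(ValueError):
            orientation_sensitivity(
                micro_fixtures["tv-graze"]["anatomy"], catalogue()[0],
                EngineConfig(perturbation_samples=0))
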