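"""Joint orientations and the eight clinical angles: phantom recovery, sign
conventions, side symmetry, rigid invariance and error paths."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import legalign as la
from legalign.alignment import condylar_tangent_line, plateau_plane, supracondylar_plane
from legalign.model import RegionLabel

from conftest import random_rigid


def test_condylar_tangent_neutral_geometry(neutral_assembly):
    line, med, lat = condylar_tangent_line(
        neutral_assembly.femur, neutral_assembly.leg_frame
    )
    # perpendicular to the sagittal symmetry plane, at the distal radius level
    assert abs(abs(line.direction[0]) - 1.0) < 1e-6
    assert abs(med[2] + 22.0) < 1e-6 and abs(lat[2] + 22.0) < 1e-6
    assert line.direction @ (neutral_assembly.side.sign * np.array([1.0, 0, 0])) > 0


def test_condylar_tangent_tilts_with_lowered_lateral_condyle(neutral_case, config):
    _, femur, tibfib, _ = neutral_case
    drop = 3.0
    v = femur.mesh.vertices.copy()
    lat_faces = femur.regions[RegionLabel.LATERAL_FEMORAL_CONDYLE]
    lat_vertices = np.unique(femur.mesh.faces[lat_faces].ravel())
    v[lat_vertices, 2] -= drop
    lowered = la.LabeledBoneModel(
        bone=femur.bone, side=femur.side,
        mesh=la.TriangleMesh(v, femur.mesh.faces.copy()),
        regions={k: i.copy() for k, i in femur.regions.items()},
    )
    asm = la.build_assembly(femur, tibfib, config)
    line, med, lat = condylar_tangent_line(lowered, asm.leg_frame)
    span = np.linalg.norm((lat - med)[:2])
    expected = np.degrees(np.arctan2(drop, span))
    tilt = np.degrees(np.arcsin(abs(la.geometry.unit(lat - med)[2])))
    assert abs(tilt - expected) < 0.1


def test_supracondylar_plane_symmetric_and_pitched(config):
    spec = la.PhantomSpec(mesh_density_mm=2.0)
    femur, tibfib, _ = la.generate_phantom(spec)
    asm = la.build_assembly(femur, tibfib, config)
    plane = supracondylar_plane(femur, asm.femoral_frame, config)
    assert abs(plane.normal[0]) < 1e-6  # normal lies in the sagittal plane
    assert plane.normal[2] > 0.999

    pitched_spec = dataclasses.replace(spec, sfj_pitch_deg=5.0)
    femur_p, _, truth_p = la.generate_phantom(pitched_spec)
    plane_p = supracondylar_plane(femur_p, asm.femoral_frame, config)
    pitch = np.degrees(np.arccos(np.clip(plane_p.normal @ [0, 0, 1.0], -1, 1)))
    assert abs(pitch - 5.0) < 0.05
    assert abs(np.degrees(np.arccos(np.clip(plane_p.normal @ truth_p.sfj_normal, -1, 1)))) < 0.05


def test_supracondylar_border_band_mode_close_to_three_point(neutral_case, config):
    _, femur, tibfib, _ = neutral_case
    asm = la.build_assembly(femur, tibfib, config)
    p3 = supracondylar_plane(femur, asm.femoral_frame, config)
    band_cfg = config.replace(sfj_mode="border_band")
    pband = supracondylar_plane(femur, asm.femoral_frame, band_cfg)
    assert np.degrees(np.arccos(np.clip(p3.normal @ pband.normal, -1, 1))) < 1.0


def test_plateau_planes_slopes_and_combination(config):
    spec = la.PhantomSpec(
        mesh_density_mm=2.0,
        posterior_slope_medial_deg=7.0,
        posterior_slope_lateral_deg=7.0,
    )
    tibfib = la.generate_phantom(spec)[1]
    medial = plateau_plane(tibfib, "MEDIAL")
    slope = np.degrees(np.arccos(np.clip(medial.normal @ [0, 0, 1.0], -1, 1)))
    assert abs(slope - 7.0) < 1e-3
    # equal symmetric compartments: combined normal equals each individual one
    combined = plateau_plane(tibfib, "COMBINED")
    lateral = plateau_plane(tibfib, "LATERAL")
    assert np.allclose(combined.normal, medial.normal, atol=1e-9)
    assert np.allclose(combined.normal, lateral.normal, atol=1e-9)


def test_medial_slope_change_leaves_lateral_angle_unchanged(config):
    base = la.PhantomSpec(mesh_density_mm=2.0, posterior_slope_lateral_deg=5.0)
    changed = dataclasses.replace(base, posterior_slope_medial_deg=10.0)
    values = []
    for spec in (base, changed):
        femur, tibfib, _ = la.generate_phantom(spec)
        asm = la.build_assembly(femur, tibfib, config)
        values.append(la.compute_slope_angles(asm, config))
    assert abs(values[0][1] - values[1][1]) < 0.05  # mLPPTA unchanged
    assert abs(values[1][0] - (90.0 - 10.0)) < 0.2  # mMPPTA follows its slope


@pytest.mark.parametrize(
    "preset, checks",
    [
        ("NEUTRAL", {"HKAA_deg": 180.0, "mLDFA_deg": 90.0, "mMPTA_deg": 90.0}),
        ("VARUS5", {"HKAA_deg": 175.0, "mLDFA_deg": 92.5, "mMPTA_deg": 87.5}),
        ("VALGUS8", {"HKAA_deg": 188.0, "mLDFA_deg": 86.0, "mMPTA_deg": 94.0}),
    ],
)
def test_coronal_sign_conventions(preset, checks, config):
    """Varus reduces HKAA and mMPTA and raises mLDFA; valgus the opposite."""
    spec, _ = la.phantom_suite(preset)[0]
    spec = dataclasses.replace(spec, mesh_density_mm=2.0)
    femur, tibfib, truth = la.generate_phantom(spec)
    report = la.analyze_leg(femur, tibfib, config)
    for name, expected in checks.items():
        assert abs(truth.angles()[name] - expected) < 1e-9
        assert abs(report.angles()[name] - expected) < 0.2


def test_version_and_torsion_labels(config):
    for version, torsion, fva_dir, tta_dir in (
        (15.0, 25.0, "ANTEVERSION", "EXTERNAL"),
        (-10.0, -15.0, "RETROVERSION", "INTERNAL"),
    ):
        spec = la.PhantomSpec(
            mesh_density_mm=2.5, femoral_version_deg=version, tibial_torsion_deg=torsion
        )
        femur, tibfib, _ = la.generate_phantom(spec)
        report = la.analyze_leg(femur, tibfib, config)
        assert abs(report.FVA_deg - abs(version)) < 0.2
        assert abs(report.TTA_deg - abs(torsion)) < 0.2
        assert report.FVA_direction.value == fva_dir
        assert report.TTA_direction.value == tta_dir


def test_axial_angles_unaffected_by_coronal_deformity(config):
    base = la.PhantomSpec(mesh_density_mm=2.0)
    varus = dataclasses.replace(base, femoral_varus_deg=5.0, tibial_varus_deg=5.0)
    reports = []
    for spec in (base, varus):
        femur, tibfib, _ = la.generate_phantom(spec)
        reports.append(la.analyze_leg(femur, tibfib, config))
    assert abs(reports[0].FVA_deg - reports[1].FVA_deg) < 0.1
    assert abs(reports[0].TTA_deg - reports[1].TTA_deg) < 0.1


def test_full_pipeline_neutral_and_deformed_recovery(neutral_case, varus_case, config):
    for _, femur, tibfib, truth in (neutral_case, varus_case):
        report = la.analyze_leg(femur, tibfib, config)
        for name, expected in truth.angles().items():
            assert abs(report.angles()[name] - expected) < 0.2, name
        assert report.FVA_direction.value == truth.FVA_direction
        assert report.TTA_direction.value == truth.TTA_direction


def test_hkaa_decomposes_into_femoral_and_tibial_contributions(config):
    """Within the small-angle regime the HKAA deviation from 180 equals the
    sum of the built coronal deformities."""
    rng = np.random.default_rng(3)
    for _ in range(3):
        fv, tv = rng.uniform(-8, 8, 2)
        spec = la.PhantomSpec(
            mesh_density_mm=2.5, femoral_varus_deg=fv, tibial_varus_deg=tv
        )
        femur, tibfib, truth = la.generate_phantom(spec)
        report = la.analyze_leg(femur, tibfib, config)
        assert abs((180.0 - report.HKAA_deg) - (fv + tv)) < 0.3


def test_side_symmetry_all_angles_and_labels(varus_spec, config):
    left_spec = dataclasses.replace(varus_spec, side=la.Side.LEFT)
    femur_r, tibfib_r, _ = la.generate_phantom(varus_spec)
    femur_l, tibfib_l, _ = la.generate_phantom(left_spec)
    right = la.analyze_leg(femur_r, tibfib_r, config)
    left = la.analyze_leg(femur_l, tibfib_l, config)
    for name in right.angles():
        assert abs(left.angles()[name] - right.angles()[name]) < 1e-3, name
    assert left.FVA_direction == right.FVA_direction
    assert left.TTA_direction == right.TTA_direction


def test_rigid_motion_invariance_of_all_angles(varus_case, config):
    _, femur, tibfib, _ = varus_case
    base = la.analyze_leg(femur, tibfib, config)
    rot, trans = random_rigid(55)
    hint = np.asarray(config.orientation_hint, float) @ rot.T
    cfg2 = config.replace(orientation_hint=tuple(map(tuple, hint)))
    moved = la.analyze_leg(femur.transformed(rot, trans), tibfib.transformed(rot, trans), cfg2)
    for name in base.angles():
        assert abs(moved.angles()[name] - base.angles()[name]) < 1e-3, name


def test_analyze_leg_deterministic(neutral_case, config):
    _, femur, tibfib, _ = neutral_case
    r1 = la.analyze_leg(femur, tibfib, config)
    r2 = la.analyze_leg(femur, tibfib, config)
    assert r1.angles() == r2.angles()
    assert r1.fit_residuals_mm == r2.fit_residuals_mm


def test_missing_trochlea_fails_in_named_stage(neutral_case, config):
    _, femur, tibfib, _ = neutral_case
    regions = {k: v.copy() for k, v in femur.regions.items()}
    del regions[RegionLabel.TROCHLEA]
    broken = la.LabeledBoneModel.__new__(la.LabeledBoneModel)
    broken.bone = femur.bone
    broken.side = femur.side
    broken.mesh = femur.mesh
    broken.regions = regions
    with pytest.raises(la.StageError, match="joint_orientations"):
        la.analyze_leg(broken, tibfib, config)


def test_extension_policies(config):
    spec = dataclasses.replace(la.PhantomSpec(), knee_flexion_deg=10.0, mesh_density_mm=2.5)
    femur, tibfib, truth = la.generate_phantom(spec)
    with pytest.raises(la.PrerequisiteError, match="strict"):
        la.analyze_leg(femur, tibfib, config.replace(extension_policy="strict"))
    auto = la.analyze_leg(femur, tibfib, config)
    assert auto.metadata["virtual_extension"]["applied"]
    assert abs(auto.HKAA_deg - truth.HKAA_deg) < 0.2
    ignored = la.analyze_leg(femur, tibfib, config.replace(extension_policy="ignore"))
    assert "warning" in ignored.metadata
    assert ignored.extension_residual_deg > 5.0
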