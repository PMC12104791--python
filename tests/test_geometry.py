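"""Geometry-core primitives: shape fits, projections, in-plane angles and
line-mesh intersections, checked against closed forms and truth-initialized
refit oracles."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

import legalign as la
from legalign.geometry import (
    plane_plane_intersection_direction,
    pooled_centroid,
    rotation_about_axis,
    unit,
)
from legalign.model import Bone, LabeledBoneModel, RegionLabel, Side, TriangleMesh

from conftest import random_rigid


# --------------------------------------------------------------------------
# sample generators and independent oracles
# --------------------------------------------------------------------------


def sphere_samples(center, radius, n=2000, cap_cos=-1.0, seed=0, sigma=0.0):
    rng = np.random.default_rng(seed)
    z = rng.uniform(cap_cos, 1.0, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - z**2)
    d = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    r = radius + sigma * rng.standard_normal(n)
    return np.asarray(center) + d * r[:, None]


def cylinder_band_samples(point, axis, radius, n=2000, seed=0, sigma=0.0):
    """Two 120-degree arc bands (condyle-like) of an infinite cylinder."""
    rng = np.random.default_rng(seed)
    axis = unit(axis)
    ref = unit(np.cross(axis, [0, 0, 1.0]) if abs(axis[2]) < 0.9 else np.cross(axis, [1.0, 0, 0]))
    e = np.cross(axis, ref)
    s = np.concatenate([rng.uniform(10, 34, n // 2), rng.uniform(-34, -10, n - n // 2)])
    phi = rng.uniform(-np.pi / 3, np.pi / 3, n)
    r = radius + sigma * rng.standard_normal(n)
    return (
        np.asarray(point)
        + np.outer(s, axis)
        + r[:, None] * (np.cos(phi)[:, None] * ref + np.sin(phi)[:, None] * e)
    )


def gauss_newton(residual, x0, steps=60):
    """Tiny truth-initialized Gauss-Newton with numeric Jacobian (oracle)."""
    x = np.asarray(x0, dtype=float)
    for _ in range(steps):
        r0 = residual(x)
        jac = np.empty((len(r0), len(x)))
        for j in range(len(x)):
            dx = np.zeros_like(x)
            dx[j] = 1e-7 * max(1.0, abs(x[j]))
            jac[:, j] = (residual(x + dx) - r0) / dx[j]
        step, *_ = np.linalg.lstsq(jac, -r0, rcond=None)
        x = x + step
        if np.linalg.norm(step) < 1e-12:
            break
    return x


# --------------------------------------------------------------------------
# sphere
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "cap_cos, tol",
    [(-1.0, 1e-9), (0.0, 1e-6)],  # full coverage / hemisphere only
    ids=["full", "hemisphere"],
)
def test_fit_sphere_exact_recovery(cap_cos, tol):
    center, radius = np.array([10.0, -20.0, 30.0]), 25.0
    pts = sphere_samples(center, radius, cap_cos=cap_cos, seed=1)
    fit = la.fit_sphere(pts)
    assert np.linalg.norm(fit.center - center) < tol
    assert abs(fit.radius_mm - radius) < tol
    assert fit.rms_mm < 1e-9


def test_fit_sphere_noisy_matches_truth_initialized_oracle():
    center, radius = np.array([10.0, -20.0, 30.0]), 25.0
    pts = sphere_samples(center, radius, n=2000, seed=3, sigma=0.1)
    fit = la.fit_sphere(pts)

    def resid(params):
        return np.linalg.norm(pts - params[:3], axis=1) - params[3]

    oracle = gauss_newton(resid, np.array([*center, radius]))
    assert np.linalg.norm(fit.center - oracle[:3]) < 1e-4
    assert abs(fit.radius_mm - oracle[3]) < 1e-4


def test_fit_sphere_rejects_coplanar_points():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.normal(size=50), rng.normal(size=50), np.zeros(50)])
    with pytest.raises(la.DegenerateGeometryError):
        la.fit_sphere(pts)


# --------------------------------------------------------------------------
# plane
# --------------------------------------------------------------------------


def test_fit_plane_flat_and_symmetric_perturbation():
    rng = np.random.default_rng(2)
    base = np.column_stack([rng.uniform(-5, 5, 100), rng.uniform(-5, 5, 100), np.full(100, 3.0)])
    flat = la.fit_plane(base, orientation_hint=[0, 0, 1])
    assert np.allclose(flat.normal, [0, 0, 1], atol=1e-12)
    assert flat.rms_mm < 1e-12

    eps = 0.25
    pts = np.vstack([base + [0, 0, eps], base - [0, 0, eps]])
    both = la.fit_plane(pts, orientation_hint=[0, 0, 1])
    assert np.allclose(both.normal, [0, 0, 1], atol=1e-9)
    assert abs(both.rms_mm - eps) < 1e-9


def test_fit_plane_recovers_construction_dihedral():
    rng = np.random.default_rng(4)
    base = np.column_stack([rng.uniform(-15, 15, 400), rng.uniform(-20, 20, 400), np.zeros(400)])
    rot = rotation_about_axis([1.0, 0, 0], np.radians(7.0))
    fit = la.fit_plane(base @ rot.T, orientation_hint=rot @ [0, 0, 1.0])
    dihedral = np.degrees(np.arccos(np.clip(fit.normal @ [0, 0, 1.0], -1, 1)))
    assert abs(dihedral - 7.0) < 1e-6


def test_fit_plane_rejects_collinear_points():
    t = np.linspace(0, 1, 30)
    pts = np.column_stack([t, 2 * t, -t])
    with pytest.raises(la.DegenerateGeometryError):
        la.fit_plane(pts)


# --------------------------------------------------------------------------
# cylinder
# --------------------------------------------------------------------------


def test_fit_cylinder_exact_two_band_recovery():
    point, axis, radius = np.array([1.0, 2.0, 3.0]), unit([1.0, 0.05, -0.02]), 22.0
    pts = cylinder_band_samples(point, axis, radius, seed=5)
    fit = la.fit_cylinder(pts)
    assert abs(abs(fit.axis.direction @ axis) - 1.0) < 1e-6  # within 1e-6 rad
    assert abs(fit.radius_mm - radius) < 1e-6
    assert fit.rms_mm < 1e-9
    # fitted axis passes through the true axis (perpendicular offset ~ 0)
    d = fit.axis.point - point
    perp = d - (d @ axis) * axis
    assert np.linalg.norm(perp) < 1e-6


def test_fit_cylinder_noisy_matches_truth_initialized_oracle():
    point, axis, radius = np.array([0.0, 0.0, 0.0]), np.array([1.0, 0, 0]), 22.0
    pts = cylinder_band_samples(point, axis, radius, seed=6, sigma=0.1)
    fit = la.fit_cylinder(pts)

    def resid(params):
        q, theta, phi, r = params[:3], params[3], params[4], params[5]
        a = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        d = pts - q
        perp = d - np.outer(d @ a, a)
        return np.linalg.norm(perp, axis=1) - r

    oracle = gauss_newton(resid, np.array([0.0, 0, 0, np.pi / 2, 0.0, radius]))
    a = np.array(
        [
            np.sin(oracle[3]) * np.cos(oracle[4]),
            np.sin(oracle[3]) * np.sin(oracle[4]),
            np.cos(oracle[3]),
        ]
    )
    assert np.arccos(np.clip(abs(fit.axis.direction @ a), -1, 1)) < 1e-3
    assert abs(fit.radius_mm - oracle[5]) < 1e-3


def test_fit_cylinder_rejects_spherical_points():
    pts = sphere_samples([0, 0, 0], 20.0, n=1500, seed=7)
    with pytest.raises(la.DegenerateGeometryError):
        la.fit_cylinder(pts)


# --------------------------------------------------------------------------
# equivariance properties of the fits
# --------------------------------------------------------------------------


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_fits_are_rigid_equivariant(seed):
    rot, trans = random_rigid(seed)
    center, radius = np.array([4.0, -2.0, 9.0]), 19.0
    sphere_pts = sphere_samples(center, radius, n=800, cap_cos=0.2, seed=seed, sigma=0.05)
    s0 = la.fit_sphere(sphere_pts)
    s1 = la.fit_sphere(sphere_pts @ rot.T + trans)
    assert np.linalg.norm(s1.center - (rot @ s0.center + trans)) < 1e-6
    assert abs(s1.rms_mm - s0.rms_mm) < 1e-9

    cyl_pts = cylinder_band_samples([0, 1, 2], [1.0, 0, 0], 22.0, n=900, seed=seed, sigma=0.05)
    c0 = la.fit_cylinder(cyl_pts)
    c1 = la.fit_cylinder(cyl_pts @ rot.T + trans)
    assert abs(abs(c1.axis.direction @ (rot @ c0.axis.direction)) - 1.0) < 1e-8
    assert abs(c1.rms_mm - c0.rms_mm) < 1e-9


# --------------------------------------------------------------------------
# projections and angles
# --------------------------------------------------------------------------


def test_project_point_along_examples():
    plane = la.Plane3([0, 0, 0], [0, 0, 1.0])
    assert np.allclose(la.project_point_along([1, 1, 5], plane, [0, 0, 1.0]), [1, 1, 0])
    on_plane = np.array([2.0, -3.0, 0.0])
    assert np.allclose(la.project_point_along(on_plane, plane, [0, 1, 1.0]), on_plane)
    # oblique: from (0,0,2) along (0,1,1)/sqrt(2) onto z=0 lands at (0,-2,0)
    hit = la.project_point_along([0, 0, 2], plane, np.array([0, 1, 1.0]) / np.sqrt(2))
    assert np.allclose(hit, [0, -2, 0], atol=1e-12)
    with pytest.raises(la.DegenerateGeometryError):
        la.project_point_along([0, 0, 2], plane, [1, 0, 0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_project_direction_properties(seed):
    rng = np.random.default_rng(seed)
    d = unit(rng.normal(size=3))
    n = unit(rng.normal(size=3))
    if abs(d @ n) > 0.999:
        return
    p = la.project_direction_onto_plane(d, n)
    assert abs(p @ n) < 1e-9
    assert abs(np.linalg.norm(p) - 1.0) < 1e-12
    # angle(d, p) is the complement of angle(d, plane)
    elevation = np.degrees(np.arcsin(np.clip(abs(d @ n), 0, 1)))
    between = np.degrees(np.arccos(np.clip(d @ p, -1, 1)))
    assert abs(between - elevation) < 1e-9


def test_angle_in_plane_examples():
    n = np.array([0.0, -1.0, 0.0])
    a, b = np.array([0.0, 0, 1.0]), np.array([1.0, 0, 0])
    assert la.angle_in_plane(a, a, n) == 360.0
    assert abs(la.angle_in_plane(a, b, n) - 90.0) < 1e-9
    assert abs(la.angle_in_plane(a, -a, n) - 180.0) < 1e-9


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_angle_in_plane_antisymmetry(seed):
    rng = np.random.default_rng(seed)
    a, b, n = (unit(rng.normal(size=3)) for _ in range(3))
    if abs(a @ n) > 0.99 or abs(b @ n) > 0.99:
        return
    total = (la.angle_in_plane(a, b, n) + la.angle_in_plane(b, a, n)) % 360.0
    assert min(total, 360.0 - total) < 1e-9


# --------------------------------------------------------------------------
# line-mesh intersections
# --------------------------------------------------------------------------


def test_line_through_icosphere_hits_twice_symmetrically():
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    mesh = TriangleMesh(np.asarray(sphere.vertices) + [1, 2, 3], np.asarray(sphere.faces))
    line = la.Line3([1, 2, 3], [0.3, -0.5, 0.8])
    hits = la.line_mesh_intersections(line, mesh)
    assert len(hits) == 2
    assert np.linalg.norm((hits[0] + hits[1]) / 2 - [1, 2, 3]) < 1e-6


def test_line_missing_mesh_returns_empty():
    sphere = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
    mesh = TriangleMesh(np.asarray(sphere.vertices), np.asarray(sphere.faces))
    hits = la.line_mesh_intersections(la.Line3([100, 0, 0], [0, 0, 1.0]), mesh)
    assert len(hits) == 0


def test_line_through_shared_edge_deduplicates():
    # two triangles sharing the edge x in [0,1], y=0, z=0; line pierces it
    vertices = np.array(
        [[0, 0, 0], [1, 0, 0], [0.5, 1, 0], [0.5, -1, 0], [0, 0, 5.0]], dtype=float
    )
    faces = np.array([[0, 1, 2], [1, 0, 3], [0, 1, 4], [2, 3, 4]])
    mesh = TriangleMesh(vertices, faces)
    line = la.Line3([0.5, 0, -1.0], [0, 0, 1.0])
    hits = la.line_mesh_intersections(line, mesh, face_subset=np.array([0, 1]))
    assert len(hits) == 1
    assert np.allclose(hits[0], [0.5, 0, 0], atol=1e-9)


# --------------------------------------------------------------------------
# region point sets and centroids
# --------------------------------------------------------------------------


def _quad_model(bone=Bone.TIBIA_FIBULA):
    """Unit square (two right triangles) labeled as a plateau, plus filler
    geometry so the mesh passes minimum-size validation."""
    vertices = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 9], [1, 0, 9], [0.5, 1, 9]],
        dtype=float,
    )
    faces = np.array([[0, 1, 2], [0, 2, 3], [4, 5, 6], [0, 4, 5]])
    mesh = TriangleMesh(vertices, faces)
    model = LabeledBoneModel.__new__(LabeledBoneModel)
    model.bone = bone
    model.side = Side.RIGHT
    model.mesh = mesh
    model.regions = {RegionLabel.MEDIAL_TIBIAL_PLATEAU: np.array([0, 1])}
    return model


def test_region_points_face_centroids_and_weights():
    model = _quad_model()
    model.regions = {RegionLabel.MEDIAL_TIBIAL_PLATEAU: np.array([0])}
    pts, w = la.region_points(model, RegionLabel.MEDIAL_TIBIAL_PLATEAU, la.PointMode.FACE_CENTROIDS)
    assert np.allclose(pts, [[2 / 3, 1 / 3, 0]])
    assert np.allclose(w, [0.5])
    model.regions = {RegionLabel.MEDIAL_TIBIAL_PLATEAU: np.array([0, 1])}
    _, w2 = la.region_points(model, RegionLabel.MEDIAL_TIBIAL_PLATEAU, la.PointMode.FACE_CENTROIDS)
    assert np.allclose(w2, [0.5, 0.5])  # equal-area triangles, equal weights


def test_surface_centroid_unit_square_and_sphere():
    model = _quad_model()
    assert np.allclose(
        la.surface_centroid(model, RegionLabel.MEDIAL_TIBIAL_PLATEAU), [0.5, 0.5, 0]
    )
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=12.0)
    model.mesh = TriangleMesh(np.asarray(sphere.vertices) + [3, -4, 5], np.asarray(sphere.faces))
    model.regions = {RegionLabel.MEDIAL_TIBIAL_PLATEAU: np.arange(len(model.mesh.faces))}
    c = la.surface_centroid(model, RegionLabel.MEDIAL_TIBIAL_PLATEAU)
    assert np.linalg.norm(c - [3, -4, 5]) < 1e-3


def test_surface_centroid_spherical_cap_matches_closed_form():
    # cap of half-angle alpha about +z: surface centroid z = R (1 + cos(alpha)) / 2
    radius, alpha = 15.0, np.radians(60.0)
    sphere = trimesh.creation.icosphere(subdivisions=5, radius=radius)
    v, f = np.asarray(sphere.vertices), np.asarray(sphere.faces)
    cap_faces = np.flatnonzero(v[f].mean(axis=1)[:, 2] >= radius * np.cos(alpha))
    model = _quad_model()
    model.mesh = TriangleMesh(v, f)
    model.regions = {RegionLabel.MEDIAL_TIBIAL_PLATEAU: cap_faces}
    c = la.surface_centroid(model, RegionLabel.MEDIAL_TIBIAL_PLATEAU)
    expected_z = radius * (1 + np.cos(alpha)) / 2
    assert abs(c[2] - expected_z) < 0.05  # tessellation error at the cap rim
    assert np.linalg.norm(c[:2]) < 1e-3


def test_pooled_centroid_explicit_arithmetic():
    model = _quad_model()
    model.regions = {
        RegionLabel.MEDIAL_TIBIAL_PLATEAU: np.array([0, 1]),  # area 1, centroid (.5,.5,0)
        RegionLabel.LATERAL_TIBIAL_PLATEAU: np.array([2]),  # area .5·? triangle at z=9
    }
    area2 = model.mesh.face_areas(np.array([2]))[0]
    c2 = model.mesh.face_centroids(np.array([2]))[0]
    expected = (1.0 * np.array([0.5, 0.5, 0.0]) + area2 * c2) / (1.0 + area2)
    got = pooled_centroid(
        model, (RegionLabel.MEDIAL_TIBIAL_PLATEAU, RegionLabel.LATERAL_TIBIAL_PLATEAU)
    )
    assert np.allclose(got, expected, atol=1e-12)


def test_plane_plane_intersection_degenerate():
    p1 = la.Plane3([0, 0, 0], [0, 0, 1.0])
    p2 = la.Plane3([0, 0, 5], [0, 1e-5, 1.0])
    with pytest.raises(la.DegenerateGeometryError):
        plane_plane_intersection_direction(p1, p2)
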