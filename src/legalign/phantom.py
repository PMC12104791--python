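"""Synthetic leg phantoms with analytic ground truth.

The generator composes analytic primitives into a labeled femur and a labeled
tibia+fibula whose true joint centres, axes and alignment angles are known in
closed form from the construction parameters — before tessellation and before
noise — so the whole measurement pipeline can be validated without any
external data.

Construction (emission frame: x to the patient's right, y anterior, z
cranial; a RIGHT leg has its lateral side at +x, a LEFT leg at -x):

* the distal femoral joint centre sits at the origin; the condylar surfaces
  are two arc bands of one cylinder whose axis runs along x through the
  origin, embedded in a closed capped-cylinder knee shell so axis-bone
  intersections behave as on a real bone;
* the trochlea is a disjoint anterior arc band (its own patch; an optional
  proximal offset realises a supracondylar-plane pitch);
* the femoral head is a labeled cap of a closed sphere around the hip point;
  the neck is a full cylindrical ring whose axis leaves the head at the
  built version angle, so the ring centroid realises the neck-femur axis
  exactly;
* coronal deformities tilt the mechanical axes — the hip point (femoral
  contribution) and the ankle assembly (tibial contribution) deviate medially
  for varus, laterally for valgus — while the joint-line structures stay at
  the knee, so varus shows up in HKAA, mLDFA and mMPTA simultaneously;
* the plateaus are planar rectangles rotated per-compartment about the
  medial-lateral axis by their posterior slopes;
* the plafond and both malleolar facets are rectangles arranged symmetrically
  about the true ankle centre; rotating the whole distal assembly about the
  vertical realises tibial torsion without moving the ankle centroid;
* knee flexion, when requested, is a rigid rotation of the entire tibia+fibula
  about the condylar axis;
* Gaussian noise is applied along vertex normals (mimicking segmentation
  surface error, and keeping labeled regions on-surface) after the truth is
  recorded.

Ground-truth angles are derived from the construction vectors with local
vector algebra that does not touch the mesh, and are therefore independent of
mesh density and noise.
"""

from __future__ import annotations

import enum
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import trimesh

from .errors import InputValidationError
from .model import Bone, LabeledBoneModel, RegionLabel, Side, TriangleMesh

# fixed anatomical constants of the construction (mm / degrees)
_CONDYLE_WIDTH = 24.0
# band parametrization: p(phi) = (s, r sin(phi), -r cos(phi)); phi = 0 is the
# most distal row, positive phi anterior, negative phi posterior
_CONDYLE_ARC = (-110.0, 30.0)  # posterior-proximal to the sulcus terminalis
_TROCHLEA_ARC = (50.0, 110.0)  # anterior band, disjoint at the sulcus
_KNEE_SHELL_MARGIN = 3.0
_NECK_PITCH_DEG = 40.0  # neck axis descent from the axial plane
_NECK_RING_LEN = 20.0
_PLATEAU_SIZE = (26.0, 40.0)  # (ml, ap) extent of each compartment
_PLATEAU_DROP = 4.0  # plateau plane below the condylar surface
_PLAFOND_SIZE = (30.0, 30.0)
_MALLEOLUS_SIZE = (14.0, 16.0)  # (ap, si) extent of each facet
_SHAFT_RADIUS = 11.0


class PhantomPreset(enum.Enum):
    NEUTRAL = "NEUTRAL"
    VARUS5 = "VARUS5"
    VALGUS8 = "VALGUS8"
    FLEXED10 = "FLEXED10"
    TORSION_SWEEP = "TORSION_SWEEP"
    NOISY = "NOISY"


@dataclass(frozen=True)
class PhantomSpec:
    """Construction parameters of a synthetic leg."""

    femur_length_mm: float = 420.0
    tibia_length_mm: float = 380.0
    head_radius_mm: float = 24.0
    condyle_radius_mm: float = 22.0
    intercondylar_halfwidth_mm: float = 12.0
    plateau_halfwidth_mm: float = 22.0
    malleolar_halfwidth_mm: float = 22.0
    femoral_varus_deg: float = 0.0
    tibial_varus_deg: float = 0.0
    posterior_slope_medial_deg: float = 0.0
    posterior_slope_lateral_deg: float = 0.0
    femoral_version_deg: float = 15.0
    tibial_torsion_deg: float = 25.0
    knee_flexion_deg: float = 0.0
    sfj_pitch_deg: float = 0.0
    side: Side = Side.RIGHT
    mesh_density_mm: float = 1.5
    noise_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "femur_length_mm",
            "tibia_length_mm",
            "head_radius_mm",
            "condyle_radius_mm",
            "intercondylar_halfwidth_mm",
            "plateau_halfwidth_mm",
            "malleolar_halfwidth_mm",
        ):
            if getattr(self, name) <= 0:
                raise InputValidationError(f"phantom spec: {name} must be > 0")
        for name in (
            "femoral_varus_deg",
            "tibial_varus_deg",
            "posterior_slope_medial_deg",
            "posterior_slope_lateral_deg",
            "femoral_version_deg",
            "tibial_torsion_deg",
            "sfj_pitch_deg",
        ):
            if abs(getattr(self, name)) > 30.0:
                raise InputValidationError(f"phantom spec: |{name}| must be <= 30")
        if not 0.0 <= self.knee_flexion_deg <= 60.0:
            raise InputValidationError("phantom spec: knee_flexion_deg in [0, 60]")
        if not 0.5 <= self.mesh_density_mm <= 5.0:
            raise InputValidationError("phantom spec: mesh_density_mm in [0.5, 5]")
        if self.noise_sigma_mm < 0:
            raise InputValidationError("phantom spec: noise_sigma_mm >= 0")
        object.__setattr__(self, "side", Side(self.side))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["side"] = self.side.value
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomSpec":
        return cls(**data)


@dataclass
class PhantomTruth:
    """Ground truth: angles plus every construction point and axis
    (emission frame, extended pose; flexed positions noted separately)."""

    HKAA_deg: float
    mLDFA_deg: float
    mMPTA_deg: float
    mPDFA_deg: float
    mMPPTA_deg: float
    mLPPTA_deg: float
    FVA_deg: float
    TTA_deg: float
    FVA_direction: str
    TTA_direction: str
    extension_residual_deg: float
    side: str
    hip_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    knee_femoral: np.ndarray = field(default_factory=lambda: np.zeros(3))
    knee_tibial: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ankle: np.ndarray = field(default_factory=lambda: np.zeros(3))
    neck_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    condylar_axis_ml: np.ndarray = field(default_factory=lambda: np.zeros(3))
    plateau_axis_ml: np.ndarray = field(default_factory=lambda: np.zeros(3))
    nfa_ml: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ima_ml: np.ndarray = field(default_factory=lambda: np.zeros(3))
    dfj_direction: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sfj_normal: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ptj_medial_normal: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ptj_lateral_normal: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ptj_combined_normal: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ankle_flexed: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def angles(self) -> dict:
        return {
            name: float(getattr(self, name))
            for name in (
                "HKAA_deg",
                "mLDFA_deg",
                "mMPTA_deg",
                "mPDFA_deg",
                "mMPPTA_deg",
                "mLPPTA_deg",
                "FVA_deg",
                "TTA_deg",
            )
        }

    def to_jsonable(self) -> dict:
        out = {}
        for key, value in asdict(self).items():
            out[key] = value.tolist() if isinstance(value, np.ndarray) else value
        return out


# --------------------------------------------------------------------------
# local vector helpers (kept independent of the measurement modules)
# --------------------------------------------------------------------------


def _u(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _rot(axis, deg):
    a = _u(axis)
    s, c = np.sin(np.radians(deg)), np.cos(np.radians(deg))
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def _proj(v, n):
    n = _u(n)
    p = np.asarray(v, dtype=float) - np.dot(v, n) * n
    return p / np.linalg.norm(p)


def _ang(a, b):
    return float(np.degrees(np.arccos(np.clip(np.dot(_u(a), _u(b)), -1.0, 1.0))))


def _frame_axes(z_raw, ml_raw):
    """(x, y, z) with z cranial along z_raw and x from ml_raw, patient-right."""
    z = _u(z_raw)
    if z[2] < 0:
        z = -z
    x = _proj(ml_raw, z)
    if x[0] < 0:
        x = -x
    y = np.cross(z, x)
    return x, y / np.linalg.norm(y), z


def _construction(spec: PhantomSpec) -> dict:
    """All true construction points/axes in the emission frame (extended)."""
    sg = spec.side.sign
    lf, lt = spec.femur_length_mm, spec.tibia_length_mm
    rc = spec.condyle_radius_mm

    knee_f = np.zeros(3)
    u_f = np.array(
        [-sg * np.sin(np.radians(spec.femoral_varus_deg)), 0.0,
         np.cos(np.radians(spec.femoral_varus_deg))]
    )  # knee -> hip
    hip = knee_f + lf * u_f

    # neck axis: head -> shaft, rotated posteriorly by the version angle about
    # the mechanical femoral axis (version is defined in the femoral axial
    # plane, so it must be built about mFA, not the global vertical) and
    # descending along mFA by the fixed neck pitch
    v = spec.femoral_version_deg
    x_mlf = _u(sg * np.array([1.0, 0, 0]) - sg * u_f[0] * u_f)
    y_anterior = sg * np.cross(u_f, x_mlf)
    axial = np.cos(np.radians(v)) * x_mlf - np.sin(np.radians(v)) * y_anterior
    d_neck = _u(
        np.cos(np.radians(_NECK_PITCH_DEG)) * axial
        - np.sin(np.radians(_NECK_PITCH_DEG)) * u_f
    )
    neck_start = 0.6 * spec.head_radius_mm
    neck_center = hip + (neck_start + 0.5 * _NECK_RING_LEN) * d_neck

    z_plat = -(rc + _PLATEAU_DROP)
    knee_t = np.array([0.0, 0.0, z_plat])
    u_t = np.array(
        [sg * np.sin(np.radians(spec.tibial_varus_deg)), 0.0,
         np.cos(np.radians(spec.tibial_varus_deg))]
    )  # ankle -> knee
    ankle = knee_t - lt * u_t

    condylar_ml = sg * np.array([1.0, 0, 0])
    plateau_ml = sg * np.array([1.0, 0, 0])
    # torsion is an axial rotation of the distal tibia about the mechanical
    # tibial axis (so TTA equals the built value exactly, decoupled from
    # coronal deformity); positive = external
    torsion_rot = _rot(u_t, -sg * spec.tibial_torsion_deg)
    ima_ml = torsion_rot @ plateau_ml

    sm = np.radians(spec.posterior_slope_medial_deg)
    sl = np.radians(spec.posterior_slope_lateral_deg)
    ptj_medial_n = np.array([0.0, -np.sin(sm), np.cos(sm)])
    ptj_lateral_n = np.array([0.0, -np.sin(sl), np.cos(sl)])

    # combined plateau plane: exact total-least-squares normal from the
    # continuous second moments of the two rectangles
    a, b = _PLATEAU_SIZE
    centers = [
        np.array([-sg * spec.plateau_halfwidth_mm, 0.0, z_plat]),
        np.array([sg * spec.plateau_halfwidth_mm, 0.0, z_plat]),
    ]
    area = a * b
    mean = 0.5 * (centers[0] + centers[1])
    scatter = np.zeros((3, 3))
    for center, slope in zip(centers, (sm, sl)):
        e1 = np.array([1.0, 0, 0])
        # in-plane AP direction: R_x(slope) applied to y-hat (posterior-down)
        e2 = np.array([0.0, np.cos(slope), np.sin(slope)])
        local = (a**2 / 12.0) * np.outer(e1, e1) + (b**2 / 12.0) * np.outer(e2, e2)
        offset = center - mean
        scatter += area * (local + np.outer(offset, offset))
    evals, evecs = np.linalg.eigh(scatter)
    ptj_combined_n = evecs[:, 0]
    if ptj_combined_n[2] < 0:
        ptj_combined_n = -ptj_combined_n

    # supracondylar plane: the three extremal points share their proximal
    # level except for the trochlear pitch offset (see generator), giving a
    # normal tilted about the ML axis by the pitch angle
    p = np.radians(spec.sfj_pitch_deg)
    sfj_n = np.array([0.0, -np.sin(p), np.cos(p)])

    # flexed ankle (flexion rotates the tibia about the condylar axis)
    flex = _rot([1.0, 0, 0], -spec.knee_flexion_deg)
    ankle_flexed = flex @ ankle

    return {
        "hip": hip,
        "knee_f": knee_f,
        "knee_t": knee_t,
        "ankle": ankle,
        "ankle_flexed": ankle_flexed,
        "neck_center": neck_center,
        "d_neck": d_neck,
        "u_f": u_f,
        "u_t": u_t,
        "condylar_ml": condylar_ml,
        "plateau_ml": plateau_ml,
        "ima_ml": ima_ml,
        "dfj_dir": np.array([1.0, 0, 0]),
        "sfj_n": sfj_n,
        "ptj_medial_n": ptj_medial_n,
        "ptj_lateral_n": ptj_lateral_n,
        "ptj_combined_n": ptj_combined_n,
        "z_plat": z_plat,
        "flex_rot": flex,
        "torsion_rot": torsion_rot,
    }


def _truth_from_construction(spec: PhantomSpec, con: dict) -> PhantomTruth:
    sg = spec.side.sign
    u_f, u_t = con["u_f"], con["u_t"]
    mla = _u(con["hip"] - con["ankle"])

    leg_x, leg_y, leg_z = _frame_axes(mla, con["condylar_ml"])
    fem_x, fem_y, fem_z = _frame_axes(u_f, con["condylar_ml"])
    tib_x, tib_y, tib_z = _frame_axes(u_t, con["plateau_ml"])
    medial_leg = -sg * leg_x

    # HKAA: medial angle between projected proximal mFA and distal mTA
    pu = _proj(u_f, leg_y)
    pv = _proj(-u_t, leg_y)
    theta = _ang(pu, pv)
    hkaa = theta if np.dot(pu + pv, medial_leg) > 0 else 360.0 - theta

    # mLDFA: proximal mFA vs lateral condylar tangent, leg coronal
    d = _proj(con["dfj_dir"], leg_y)
    if np.dot(d, -medial_leg) < 0:
        d = -d
    mldfa = _ang(pu, d)

    # mMPTA: distal mTA vs medial combined-plateau trace, leg coronal
    trace = np.cross(con["ptj_combined_n"], leg_y)
    trace = trace / np.linalg.norm(trace)
    if np.dot(trace, medial_leg) < 0:
        trace = -trace
    mmpta = _ang(_proj(-u_t, leg_y), trace)

    # mPDFA: proximal mFA vs posterior SFJ trace, femoral sagittal
    trace = np.cross(con["sfj_n"], fem_x)
    trace = trace / np.linalg.norm(trace)
    if np.dot(trace, -fem_y) < 0:
        trace = -trace
    mpdfa = _ang(_proj(u_f, fem_x), trace)

    # slope angles: distal mTA vs posterior compartment trace, tibial sagittal
    slopes = []
    for key in ("ptj_medial_n", "ptj_lateral_n"):
        trace = np.cross(con[key], tib_x)
        trace = trace / np.linalg.norm(trace)
        if np.dot(trace, -tib_y) < 0:
            trace = -trace
        slopes.append(_ang(_proj(-u_t, tib_x), trace))

    def acute(reference, measured, normal):
        pa, pb = _proj(reference, normal), _proj(measured, normal)
        psi = np.degrees(np.arctan2(np.dot(np.cross(pa, pb), normal), np.dot(pa, pb)))
        if psi > 90.0:
            psi -= 180.0
        elif psi < -90.0:
            psi += 180.0
        return abs(float(psi)), sg * float(psi)

    fva, fva_signed = acute(con["condylar_ml"], con["d_neck"], fem_z)
    tta, tta_signed = acute(con["plateau_ml"], con["ima_ml"], tib_z)

    # extension residual of the emitted (possibly flexed) pose
    u_t_flexed = _u(con["flex_rot"] @ u_t)
    mla_flexed = _u(con["hip"] - con["ankle_flexed"])
    lx, _, _ = _frame_axes(mla_flexed, con["condylar_ml"])
    pf = u_f - np.dot(u_f, lx) * lx
    pt = u_t_flexed - np.dot(u_t_flexed, lx) * lx
    residual = float(
        np.degrees(
            np.arccos(
                np.clip(abs(np.dot(pf, pt)) / (np.linalg.norm(pf) * np.linalg.norm(pt)), -1, 1)
            )
        )
    )

    return PhantomTruth(
        HKAA_deg=float(hkaa),
        mLDFA_deg=float(mldfa),
        mMPTA_deg=float(mmpta),
        mPDFA_deg=float(mpdfa),
        mMPPTA_deg=float(slopes[0]),
        mLPPTA_deg=float(slopes[1]),
        FVA_deg=float(fva),
        TTA_deg=float(tta),
        FVA_direction="ANTEVERSION" if fva_signed <= 0 else "RETROVERSION",
        TTA_direction="EXTERNAL" if tta_signed <= 0 else "INTERNAL",
        extension_residual_deg=residual,
        side=spec.side.value,
        hip_center=con["hip"],
        knee_femoral=con["knee_f"],
        knee_tibial=con["knee_t"],
        ankle=con["ankle"],
        neck_center=con["neck_center"],
        condylar_axis_ml=con["condylar_ml"],
        plateau_axis_ml=con["plateau_ml"],
        nfa_ml=con["d_neck"],
        ima_ml=con["ima_ml"],
        dfj_direction=con["dfj_dir"],
        sfj_normal=con["sfj_n"],
        ptj_medial_normal=con["ptj_medial_n"],
        ptj_lateral_normal=con["ptj_lateral_n"],
        ptj_combined_normal=con["ptj_combined_n"],
        ankle_flexed=con["ankle_flexed"],
    )


# --------------------------------------------------------------------------
# tessellation helpers
# --------------------------------------------------------------------------


def _breaks(lo: float, hi: float, step: float, include=()) -> np.ndarray:
    anchors = sorted({lo, hi, *(x for x in include if lo < x < hi)})
    out = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        n = max(1, int(np.ceil((b - a) / step)))
        out.append(np.linspace(a, b, n + 1)[:-1])
    out.append(np.array([anchors[-1]]))
    return np.concatenate(out)


def _grid_faces(nu: int, nv: int, wrap_v: bool = False):
    """Triangulate a (nu x nv) vertex grid; optionally wrap the v direction."""
    faces = []
    mv = nv if wrap_v else nv - 1
    for i in range(nu - 1):
        for j in range(mv):
            j1 = (j + 1) % nv
            a = i * nv + j
            b = i * nv + j1
            c = (i + 1) * nv + j
            d = (i + 1) * nv + j1
            faces.append((a, b, d))
            faces.append((a, d, c))
    return np.asarray(faces, dtype=np.int64)


class _MeshBuilder:
    def __init__(self):
        self.vertices = []
        self.faces = []
        self.regions: dict = {}

    def add(self, vertices, faces, region: RegionLabel | None = None, face_mask=None):
        offset_v = sum(len(v) for v in self.vertices)
        offset_f = sum(len(f) for f in self.faces)
        self.vertices.append(np.asarray(vertices, dtype=float))
        faces = np.asarray(faces, dtype=np.int64) + offset_v
        self.faces.append(faces)
        if region is not None:
            idx = np.arange(len(faces)) if face_mask is None else np.flatnonzero(face_mask)
            self.regions.setdefault(region, []).append(idx + offset_f)

    def build(self, bone: Bone, side: Side) -> LabeledBoneModel:
        mesh = TriangleMesh(np.vstack(self.vertices), np.vstack(self.faces))
        regions = {k: np.concatenate(v) for k, v in self.regions.items()}
        return LabeledBoneModel(bone=bone, side=side, mesh=mesh, regions=regions)


def _cylinder_band(
    point, axis, ref, s_breaks, phi_breaks_deg, radius, wrap: bool = False
):
    """Vertices/faces of a cylinder band: p(s, phi) = point + s*axis +
    r(cos phi * d + sin phi * e) with d = ref, e = axis x ref."""
    axis, d = _u(axis), _u(ref)
    e = np.cross(axis, d)
    phis = np.radians(phi_breaks_deg)
    ss, pp = np.meshgrid(s_breaks, phis, indexing="ij")
    pts = (
        np.asarray(point)[None, :]
        + ss.reshape(-1, 1) * axis
        + radius * (np.cos(pp).reshape(-1, 1) * d + np.sin(pp).reshape(-1, 1) * e)
    )
    faces = _grid_faces(len(s_breaks), len(phis), wrap_v=wrap)
    return pts, faces


def _disk_fan(center, axis, ref, radius, phi_breaks_deg):
    axis, d = _u(axis), _u(ref)
    e = np.cross(axis, d)
    phis = np.radians(phi_breaks_deg)
    ring = (
        np.asarray(center)[None, :]
        + radius * (np.cos(phis)[:, None] * d + np.sin(phis)[:, None] * e)
    )
    pts = np.vstack([np.asarray(center)[None, :], ring])
    n = len(phis)
    faces = np.array([(0, 1 + i, 1 + (i + 1) % n) for i in range(n)], dtype=np.int64)
    return pts, faces


def _rect_patch(center, e1, e2, size1, size2, step, rotation=None, pivot=None):
    """Planar rectangle grid centered at ``center`` spanned by e1/e2."""
    u = _breaks(-size1 / 2, size1 / 2, step)
    v = _breaks(-size2 / 2, size2 / 2, step)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    pts = (
        np.asarray(center)[None, :]
        + uu.reshape(-1, 1) * _u(e1)
        + vv.reshape(-1, 1) * _u(e2)
    )
    if rotation is not None:
        pivot = np.asarray(center if pivot is None else pivot, dtype=float)
        pts = (pts - pivot) @ np.asarray(rotation).T + pivot
    return pts, _grid_faces(len(u), len(v))


def _capped_cylinder(builder, p0, p1, radius, step):
    """Closed unlabeled tube between two points."""
    axis = _u(np.asarray(p1) - np.asarray(p0))
    ref = _u(np.cross(axis, [1.0, 0, 0]) if abs(axis[2]) > 0.9 else np.cross(axis, [0, 0, 1.0]))
    length = float(np.linalg.norm(np.asarray(p1) - np.asarray(p0)))
    s = _breaks(0.0, length, step)
    nphi = max(8, int(np.ceil(2 * np.pi * radius / step)))
    phi = np.linspace(0.0, 360.0, nphi, endpoint=False)
    v, f = _cylinder_band(p0, axis, ref, s, phi, radius, wrap=True)
    builder.add(v, f)
    for center, sign in ((p0, -1.0), (p1, 1.0)):
        v, f = _disk_fan(center, sign * axis, ref, radius, phi)
        builder.add(v, f)


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------


def _build_femur(spec: PhantomSpec, con: dict) -> LabeledBoneModel:
    sg = spec.side.sign
    step = spec.mesh_density_mm
    coarse = min(5.0, max(3.0 * step, 4.0))
    rc = spec.condyle_radius_mm
    h = spec.intercondylar_halfwidth_mm
    w_shell = h + _CONDYLE_WIDTH + _KNEE_SHELL_MARGIN
    builder = _MeshBuilder()

    # knee shell: closed capped cylinder about the condylar axis; the condyle
    # arc bands are labeled subsets of its faces
    deg_step = np.degrees(step / rc)
    phi = _breaks(
        -180.0,
        180.0,
        deg_step,
        include=(*_CONDYLE_ARC, *_TROCHLEA_ARC, 0.0),
    )[:-1]  # drop duplicate seam value; band wraps
    s = _breaks(-w_shell, w_shell, step, include=(-h - _CONDYLE_WIDTH, -h, h, h + _CONDYLE_WIDTH))
    v, f = _cylinder_band([0.0, 0, 0], [1.0, 0, 0], [0.0, 0, -1.0], s, phi, rc, wrap=True)
    # classify faces by centroid (s, phi)
    tri = v[f]
    cent = tri.mean(axis=1)
    cphi = np.degrees(np.arctan2(cent[:, 1], -cent[:, 2]))  # 0 = distal, + anterior
    cs = cent[:, 0]
    in_arc = (cphi > _CONDYLE_ARC[0]) & (cphi < _CONDYLE_ARC[1])
    med_band = (cs > -h - _CONDYLE_WIDTH) & (cs < -h)
    lat_band = (cs > h) & (cs < h + _CONDYLE_WIDTH)
    medial_mask = in_arc & (med_band if sg > 0 else lat_band)
    lateral_mask = in_arc & (lat_band if sg > 0 else med_band)
    builder.add(v, f, RegionLabel.MEDIAL_FEMORAL_CONDYLE, medial_mask)
    # faces may carry at most one label; register the lateral set on the same patch
    offset_f = len(builder.faces[0]) - len(f)
    builder.regions.setdefault(RegionLabel.LATERAL_FEMORAL_CONDYLE, []).append(
        np.flatnonzero(lateral_mask) + offset_f
    )
    nphi_cap = max(12, int(np.ceil(2 * np.pi * rc / step)))
    cap_phi = np.linspace(0.0, 360.0, nphi_cap, endpoint=False)
    for x_end, sign in ((-w_shell, -1.0), (w_shell, 1.0)):
        cv, cf = _disk_fan([x_end, 0, 0], [sign, 0, 0], [0.0, 0, -1.0], rc, cap_phi)
        builder.add(cv, cf)

    # trochlea: separate anterior arc band (offset proximally for SFJ pitch so
    # the closed shell is left intact); pitch is defined about the tangent-
    # point separation of the extremal rows
    p = np.radians(spec.sfj_pitch_deg)
    y_troch = rc * np.sin(np.radians(_TROCHLEA_ARC[1]))  # anterior extremal row
    y_cond = rc * np.sin(np.radians(_CONDYLE_ARC[0]))  # posterior extremal row
    dz = np.tan(p) * (y_troch - y_cond)
    w_t = max(h - 1.0, 6.0)
    s_t = _breaks(-w_t, w_t, step)
    phi_t = _breaks(_TROCHLEA_ARC[0], _TROCHLEA_ARC[1], deg_step)
    v, f = _cylinder_band([0.0, 0, dz], [1.0, 0, 0], [0.0, 0, -1.0], s_t, phi_t, rc)
    builder.add(v, f, RegionLabel.TROCHLEA)

    # femoral head: closed sphere, articular cap labeled
    r_h = spec.head_radius_mm
    sub = int(np.clip(round(np.log2(1.0514 * r_h / step)), 1, 5))
    sphere = trimesh.creation.icosphere(subdivisions=sub, radius=r_h)
    sv = np.asarray(sphere.vertices) + con["hip"]
    sf = np.asarray(sphere.faces)
    cap_axis = -con["d_neck"]
    cosang = (_u_rows(sv[sf].mean(axis=1) - con["hip"]) @ cap_axis)
    builder.add(sv, sf, RegionLabel.FEMORAL_HEAD, cosang >= np.cos(np.radians(85.0)))

    # neck: full ring (labeled) + end caps, centroid exactly on the neck axis
    neck_r = 0.55 * r_h
    t0 = 0.6 * r_h
    s_n = _breaks(t0, t0 + _NECK_RING_LEN, step)
    ref_n = _u(np.cross(con["d_neck"], [0, 0, 1.0]))
    nphi_n = max(10, int(np.ceil(2 * np.pi * neck_r / step)))
    phi_n = np.linspace(0.0, 360.0, nphi_n, endpoint=False)
    v, f = _cylinder_band(con["hip"], con["d_neck"], ref_n, s_n, phi_n, neck_r, wrap=True)
    builder.add(v, f, RegionLabel.FEMORAL_NECK)
    for t_end, sign in ((t0, -1.0), (t0 + _NECK_RING_LEN, 1.0)):
        cv, cf = _disk_fan(
            con["hip"] + t_end * con["d_neck"], sign * con["d_neck"], ref_n, neck_r, phi_n
        )
        builder.add(cv, cf)

    # shaft (inert): coarse closed tube from the knee shell toward the neck base
    p0 = np.array([0.0, 0.0, 0.8 * rc])
    p1 = con["hip"] + (t0 + _NECK_RING_LEN) * con["d_neck"] + np.array([0.0, 0, 5.0])
    _capped_cylinder(builder, p0, p1, _SHAFT_RADIUS, coarse)

    return builder.build(Bone.FEMUR, spec.side)


def _u_rows(m):
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def _build_tibfib(spec: PhantomSpec, con: dict) -> LabeledBoneModel:
    sg = spec.side.sign
    step = spec.mesh_density_mm
    coarse = min(5.0, max(3.0 * step, 4.0))
    builder = _MeshBuilder()
    z_plat = con["z_plat"]

    # plateaus: per-compartment rectangles rotated about their centroids by
    # the posterior slopes
    a, b = _PLATEAU_SIZE
    for label, x_sign, slope in (
        (RegionLabel.MEDIAL_TIBIAL_PLATEAU, -sg, spec.posterior_slope_medial_deg),
        (RegionLabel.LATERAL_TIBIAL_PLATEAU, sg, spec.posterior_slope_lateral_deg),
    ):
        center = np.array([x_sign * spec.plateau_halfwidth_mm, 0.0, z_plat])
        rot = _rot([1.0, 0, 0], slope)
        v, f = _rect_patch(center, [1.0, 0, 0], [0, 1.0, 0], a, b, step, rotation=rot)
        builder.add(v, f, label)

    # distal articular assembly: plafond + malleolar facets arranged
    # symmetrically about the true ankle centre, rotated by the torsion
    ankle = con["ankle"]
    rt = con["torsion_rot"]
    v, f = _rect_patch(
        ankle, rt @ np.array([1.0, 0, 0]), rt @ np.array([0, 1.0, 0]),
        _PLAFOND_SIZE[0], _PLAFOND_SIZE[1], step,
    )
    builder.add(v, f, RegionLabel.TIBIAL_PLAFOND)
    for label, x_sign in (
        (RegionLabel.MEDIAL_MALLEOLUS_FACET, -sg),
        (RegionLabel.LATERAL_MALLEOLUS_FACET, sg),
    ):
        center = ankle + rt @ np.array([x_sign * spec.malleolar_halfwidth_mm, 0.0, 0.0])
        v, f = _rect_patch(
            center, rt @ np.array([0, 1.0, 0]), np.array([0, 0, 1.0]),
            _MALLEOLUS_SIZE[0], _MALLEOLUS_SIZE[1], step,
        )
        builder.add(v, f, label)

    # shaft (inert)
    _capped_cylinder(
        builder,
        np.array([0.0, 0.0, z_plat - 3.0]),
        ankle + np.array([0.0, 0.0, _MALLEOLUS_SIZE[1]]),
        _SHAFT_RADIUS - 1.0,
        coarse,
    )
    model = builder.build(Bone.TIBIA_FIBULA, spec.side)

    flex = con["flex_rot"]
    if spec.knee_flexion_deg != 0.0:
        model = model.transformed(flex, np.zeros(3))
    return model


def _apply_noise(model: LabeledBoneModel, sigma: float, rng) -> LabeledBoneModel:
    tm = trimesh.Trimesh(
        vertices=model.mesh.vertices, faces=model.mesh.faces, process=False
    )
    normals = np.asarray(tm.vertex_normals)
    bad = ~np.isfinite(normals).all(axis=1)
    if bad.any():
        normals[bad] = [0.0, 0.0, 1.0]
    disp = rng.standard_normal(len(normals)) * sigma
    vertices = model.mesh.vertices + normals * disp[:, None]
    return LabeledBoneModel(
        bone=model.bone,
        side=model.side,
        mesh=TriangleMesh(vertices, model.mesh.faces.copy()),
        regions={k: v.copy() for k, v in model.regions.items()},
    )


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[LabeledBoneModel, LabeledBoneModel, PhantomTruth]:
    """Generate a labeled femur, a labeled tibia+fibula and their ground truth.

    Truth is derived from the construction parameters before tessellation and
    noise, so it is invariant to ``mesh_density_mm`` and ``noise_sigma_mm``.
    """
    con = _construction(spec)
    truth = _truth_from_construction(spec, con)
    femur = _build_femur(spec, con)
    tibfib = _build_tibfib(spec, con)
    if spec.noise_sigma_mm > 0:
        rng = np.random.default_rng(spec.seed)
        femur = _apply_noise(femur, spec.noise_sigma_mm, rng)
        tibfib = _apply_noise(tibfib, spec.noise_sigma_mm, rng)
    return femur, tibfib, truth


def phantom_suite(preset: PhantomPreset | str) -> list[tuple[PhantomSpec, float]]:
    """Fixture specs per preset, each with its documented angle tolerance
    (degrees) for pipeline-recovery checks."""
    preset = PhantomPreset(preset) if not isinstance(preset, PhantomPreset) else preset
    base = PhantomSpec()
    if preset is PhantomPreset.NEUTRAL:
        return [(base, 0.2)]
    if preset is PhantomPreset.VARUS5:
        return [
            (
                replace(
                    base,
                    femoral_varus_deg=2.5,
                    tibial_varus_deg=2.5,
                    posterior_slope_medial_deg=7.0,
                    posterior_slope_lateral_deg=7.0,
                ),
                0.2,
            )
        ]
    if preset is PhantomPreset.VALGUS8:
        return [
            (
                replace(
                    base,
                    femoral_varus_deg=-4.0,
                    tibial_varus_deg=-4.0,
                    posterior_slope_medial_deg=7.0,
                    posterior_slope_lateral_deg=7.0,
                ),
                0.2,
            )
        ]
    if preset is PhantomPreset.FLEXED10:
        return [(replace(base, knee_flexion_deg=10.0), 0.2)]
    if preset is PhantomPreset.TORSION_SWEEP:
        return [
            (replace(base, tibial_torsion_deg=t), 0.2)
            for t in (-20.0, -10.0, 0.0, 10.0, 20.0, 30.0)
        ]
    if preset is PhantomPreset.NOISY:
        return [
            (replace(base, noise_sigma_mm=0.2, seed=seed), 1.0) for seed in range(10)
        ]
    raise InputValidationError(f"unknown preset {preset}")


def write_truth(truth: PhantomTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1, sort_keys=True)
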