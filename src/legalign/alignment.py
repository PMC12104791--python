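"""Joint orientations and the eight clinical alignment angles.

Every angle is measured between projections in the anatomical plane of the
prescribed coordinate system:

========  =====================  ==========================================
angle     plane                  rays
========  =====================  ==========================================
HKAA      leg coronal            proximal mFA vs distal mTA, medial side
mLDFA     leg coronal            proximal mFA vs lateral condylar tangent
mMPTA     leg coronal            distal mTA vs medial trace of the combined
                                 plateau plane
mPDFA     femoral sagittal       proximal mFA vs posterior trace of the
                                 supracondylar-trochlear plane
mMPPTA    tibial sagittal        distal mTA vs posterior trace of the medial
                                 plateau plane
mLPPTA    tibial sagittal        distal mTA vs posterior trace of the lateral
                                 plateau plane
FVA       femoral axial          neck-femur axis vs condylar ML axis (acute)
TTA       tibial axial           intermalleolar vs plateau ML axis (acute)
========  =====================  ==========================================

Sign conventions (side-aware, so mirrored left and right legs report equal
values): varus gives HKAA < 180, mLDFA > 90 and mMPTA < 90; posterior tibial
slope gives mMPPTA/mLPPTA < 90; a distal femur flexed relative to the
mechanical axis gives mPDFA > 90.  FVA/TTA are acute angles in [0, 90] with
ANTEVERSION/RETROVERSION resp. EXTERNAL/INTERNAL labels.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from ._version import __version__ as _version
from .config import RunConfig
from .errors import (
    DegenerateGeometryError,
    LegalignError,
    PrerequisiteError,
    StageError,
)
from .frames import Frame, LegAssembly, build_assembly, virtual_extend
from .geometry import (
    Line3,
    Plane3,
    PointMode,
    fit_plane,
    plane_plane_intersection_direction,
    region_points,
    unit,
)
from .model import AlignmentReport, Direction, LabeledBoneModel, RegionLabel

_TIE_EPS_MM = 1e-9


def _medial(frame: Frame, side) -> np.ndarray:
    """In-frame medial direction: x points to the patient's right, so the
    medial side of a RIGHT leg is -x and of a LEFT leg +x."""
    return -side.sign * frame.x


def _extremal_point(
    model: LabeledBoneModel, region: RegionLabel, frame: Frame, sign: float
) -> np.ndarray:
    """Most distal (sign=-1) or proximal (sign=+1) region vertex measured
    along the frame's z axis; ties within 1e-9 mm are averaged so that flat
    extremes resolve deterministically and symmetrically."""
    points, _ = region_points(model, region, PointMode.VERTICES)
    score = sign * (points - frame.origin) @ frame.z
    best = score.max()
    tied = points[score >= best - _TIE_EPS_MM]
    return tied.mean(axis=0)


def condylar_tangent_line(
    femur: LabeledBoneModel, ref_frame: Frame
) -> tuple[Line3, np.ndarray, np.ndarray]:
    """Distal femoral condylar joint orientation (DFJ): the tangent line
    joining the most distal point of each condyle in the reference frame.

    Returns the line (directed medial -> lateral) and both endpoints.
    """
    medial_pt = _extremal_point(femur, RegionLabel.MEDIAL_FEMORAL_CONDYLE, ref_frame, -1.0)
    lateral_pt = _extremal_point(femur, RegionLabel.LATERAL_FEMORAL_CONDYLE, ref_frame, -1.0)
    if np.linalg.norm(lateral_pt - medial_pt) < 1.0:
        raise DegenerateGeometryError("condylar tangent endpoints nearly coincide")
    return Line3(medial_pt, lateral_pt - medial_pt), medial_pt, lateral_pt


def supracondylar_plane(
    femur: LabeledBoneModel, ref_frame: Frame, config: RunConfig | None = None
) -> Plane3:
    """Supracondylar-trochlear femoral joint orientation (SFJ).

    Default: the plane through the single most proximal point of each of the
    three regions (trochlea, medial and lateral condyle) in the reference
    frame, matching the figure construction.  ``sfj.mode = border_band``
    instead least-squares-fits a plane to the proximal border band (top
    fraction of each region's z-range).
    """
    config = config or RunConfig()
    regions = (
        RegionLabel.TROCHLEA,
        RegionLabel.MEDIAL_FEMORAL_CONDYLE,
        RegionLabel.LATERAL_FEMORAL_CONDYLE,
    )
    if config.sfj_mode == "border_band":
        band = []
        for region in regions:
            points, _ = region_points(femur, region, PointMode.VERTICES)
            z = (points - ref_frame.origin) @ ref_frame.z
            cut = z.max() - config.sfj_border_band_fraction * max(z.max() - z.min(), 1e-9)
            band.append(points[z >= cut])
        return fit_plane(np.vstack(band), orientation_hint=ref_frame.z)
    p1, p2, p3 = (_extremal_point(femur, r, ref_frame, +1.0) for r in regions)
    normal = np.cross(p2 - p1, p3 - p1)
    if np.linalg.norm(normal) < 1e-6:
        raise DegenerateGeometryError("supracondylar points are collinear")
    normal = unit(normal)
    if float(np.dot(normal, ref_frame.z)) < 0:
        normal = -normal
    return Plane3((p1 + p2 + p3) / 3.0, normal, 0.0)


_PLATEAU_REGIONS = {
    "MEDIAL": (RegionLabel.MEDIAL_TIBIAL_PLATEAU,),
    "LATERAL": (RegionLabel.LATERAL_TIBIAL_PLATEAU,),
    "COMBINED": (
        RegionLabel.MEDIAL_TIBIAL_PLATEAU,
        RegionLabel.LATERAL_TIBIAL_PLATEAU,
    ),
}


def plateau_plane(
    tibfib: LabeledBoneModel, which: str, proximal_hint=None
) -> Plane3:
    """Tibial plateau joint orientation (PTJ): an area-weighted
    total-least-squares plane over the selected compartment(s), normal
    oriented proximally."""
    try:
        regions = _PLATEAU_REGIONS[which.upper()]
    except KeyError:
        raise LegalignError(f"plateau_plane: which must be MEDIAL|LATERAL|COMBINED, got {which!r}")
    pts, wts = [], []
    for region in regions:
        p, w = region_points(tibfib, region, PointMode.FACE_CENTROIDS)
        pts.append(p)
        wts.append(w)
    if proximal_hint is None:
        proximal_hint = np.array([0.0, 0.0, 1.0])
    return fit_plane(np.vstack(pts), np.concatenate(wts), orientation_hint=proximal_hint)


@dataclass
class JointOrientationSet:
    DFJ: Line3
    DFJ_medial_point: np.ndarray
    DFJ_lateral_point: np.ndarray
    SFJ: Plane3
    PTJ_medial: Plane3
    PTJ_lateral: Plane3
    PTJ_combined: Plane3
    NFA: Line3
    IMA: Line3


def joint_orientations(
    assembly: LegAssembly, config: RunConfig | None = None
) -> JointOrientationSet:
    """All consensus joint orientations.

    The condylar tangent is picked in the leg frame (it feeds coronal
    angles); the supracondylar extremes in the femoral frame (it feeds the
    femoral sagittal angle).
    """
    config = config or RunConfig()
    dfj, med_pt, lat_pt = condylar_tangent_line(assembly.femur, assembly.leg_frame)
    sfj = supracondylar_plane(assembly.femur, assembly.femoral_frame, config)
    hint = assembly.tibial_frame.z
    return JointOrientationSet(
        DFJ=dfj,
        DFJ_medial_point=med_pt,
        DFJ_lateral_point=lat_pt,
        SFJ=sfj,
        PTJ_medial=plateau_plane(assembly.tibfib, "MEDIAL", hint),
        PTJ_lateral=plateau_plane(assembly.tibfib, "LATERAL", hint),
        PTJ_combined=plateau_plane(assembly.tibfib, "COMBINED", hint),
        NFA=assembly.ml_axes.neck_femur,
        IMA=assembly.ml_axes.intermalleolar,
    )


# --------------------------------------------------------------------------
# angle helpers
# --------------------------------------------------------------------------


def _project(direction, normal) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    n = unit(normal)
    p = d - float(np.dot(d, n)) * n
    norm = np.linalg.norm(p)
    if norm < 1e-9:
        raise DegenerateGeometryError("direction degenerate under projection")
    return p / norm


def _ray_angle_deg(a, b) -> float:
    return float(np.degrees(np.arccos(np.clip(float(np.dot(a, b)), -1.0, 1.0))))


def _oriented_trace(plane: Plane3, section_normal, toward) -> np.ndarray:
    """Intersection direction of ``plane`` with the anatomical plane of
    normal ``section_normal``, oriented toward ``toward``."""
    trace = plane_plane_intersection_direction(plane, Plane3(np.zeros(3), section_normal))
    return trace if float(np.dot(trace, toward)) >= 0 else -trace


def _check_extension(assembly: LegAssembly, config: RunConfig) -> None:
    if assembly.extension_residual_deg > config.extension_auto_threshold_deg:
        raise PrerequisiteError(
            "knee-extension prerequisite violated: sagittal residual "
            f"{assembly.extension_residual_deg:.2f} deg exceeds "
            f"{config.extension_auto_threshold_deg} deg",
            residual_deg=assembly.extension_residual_deg,
        )


def compute_hkaa(assembly: LegAssembly, config: RunConfig | None = None) -> float:
    """Hip-knee-ankle angle: the medial angle between projected mFA and mTA
    in the leg coronal plane.  180 = straight, < 180 varus, > 180 valgus."""
    config = config or RunConfig()
    _check_extension(assembly, config)
    n = assembly.leg_frame.coronal_normal
    u = _project(assembly.axes.mFA.direction, n)  # knee -> hip
    v = _project(-assembly.axes.mTA.direction, n)  # knee -> ankle
    theta = _ray_angle_deg(u, v)
    medial = _medial(assembly.leg_frame, assembly.side)
    opens_medially = float(np.dot(u + v, medial)) > 0
    return theta if opens_medially else 360.0 - theta


def compute_mldfa(
    assembly: LegAssembly,
    config: RunConfig | None = None,
    orientations: JointOrientationSet | None = None,
) -> float:
    """Mechanical lateral distal femoral angle: lateral angle between the
    proximal mFA and the condylar tangent in the leg coronal plane."""
    config = config or RunConfig()
    dfj = (
        orientations.DFJ
        if orientations is not None
        else condylar_tangent_line(assembly.femur, assembly.leg_frame)[0]
    )
    n = assembly.leg_frame.coronal_normal
    u = _project(assembly.axes.mFA.direction, n)
    lateral = -_medial(assembly.leg_frame, assembly.side)
    d = _project(dfj.direction, n)
    if float(np.dot(d, lateral)) < 0:
        d = -d
    return _ray_angle_deg(u, d)


def compute_mmpta(
    assembly: LegAssembly,
    config: RunConfig | None = None,
    orientations: JointOrientationSet | None = None,
) -> float:
    """Mechanical medial proximal tibial angle: medial angle between the
    distal mTA and the trace of the combined plateau plane in the leg
    coronal plane."""
    config = config or RunConfig()
    ptj = (
        orientations.PTJ_combined
        if orientations is not None
        else plateau_plane(assembly.tibfib, "COMBINED", assembly.tibial_frame.z)
    )
    frame = assembly.leg_frame
    medial = _medial(frame, assembly.side)
    trace = _oriented_trace(ptj, frame.coronal_normal, medial)
    t = _project(-assembly.axes.mTA.direction, frame.coronal_normal)  # distal
    return _ray_angle_deg(t, trace)


def compute_mpdfa(
    assembly: LegAssembly,
    config: RunConfig | None = None,
    orientations: JointOrientationSet | None = None,
) -> float:
    """Mechanical posterior distal femoral angle: posterior angle between the
    proximal mFA and the supracondylar-plane trace in the femoral sagittal
    plane."""
    config = config or RunConfig()
    sfj = (
        orientations.SFJ
        if orientations is not None
        else supracondylar_plane(assembly.femur, assembly.femoral_frame, config)
    )
    frame = assembly.femoral_frame
    posterior = -frame.y
    trace = _oriented_trace(sfj, frame.sagittal_normal, posterior)
    u = _project(assembly.axes.mFA.direction, frame.sagittal_normal)
    return _ray_angle_deg(u, trace)


def compute_slope_angles(
    assembly: LegAssembly,
    config: RunConfig | None = None,
    orientations: JointOrientationSet | None = None,
) -> tuple[float, float]:
    """Sagittal plateau angles (mMPPTA, mLPPTA): posterior angle between the
    distal mTA and each compartment plane's trace in the tibial sagittal
    plane.  A posterior slope of s degrees gives 90 - s."""
    config = config or RunConfig()
    frame = assembly.tibial_frame
    posterior = -frame.y
    t = _project(-assembly.axes.mTA.direction, frame.sagittal_normal)  # distal
    out = []
    for which in ("MEDIAL", "LATERAL"):
        if orientations is not None:
            plane = orientations.PTJ_medial if which == "MEDIAL" else orientations.PTJ_lateral
        else:
            plane = plateau_plane(assembly.tibfib, which, frame.z)
        trace = _oriented_trace(plane, frame.sagittal_normal, posterior)
        out.append(_ray_angle_deg(t, trace))
    return out[0], out[1]


def _acute_axial_angle(
    reference_ml, measured_ml, axial_normal, side_sign: int
) -> tuple[float, float]:
    """Acute angle between two medial->lateral axes projected on an axial
    plane, plus the side-adjusted signed angle used for direction labels."""
    a = _project(reference_ml, axial_normal)
    b = _project(measured_ml, axial_normal)
    psi = np.degrees(
        np.arctan2(float(np.dot(np.cross(a, b), axial_normal)), float(np.dot(a, b)))
    )
    # fold to the acute line-angle in [-90, 90]
    if psi > 90.0:
        psi -= 180.0
    elif psi < -90.0:
        psi += 180.0
    return abs(float(psi)), side_sign * float(psi)


def compute_fva(
    assembly: LegAssembly, config: RunConfig | None = None
) -> tuple[float, Direction]:
    """Femoral version: acute angle between the projections of the neck-femur
    axis and the condylar central ML axis on the femoral axial plane."""
    config = config or RunConfig()
    angle, signed = _acute_axial_angle(
        assembly.ml_axes.distal_femoral.direction,
        assembly.ml_axes.neck_femur.direction,
        assembly.femoral_frame.axial_normal,
        assembly.side.sign,
    )
    direction = Direction.ANTEVERSION if signed <= 0 else Direction.RETROVERSION
    return angle, direction


def compute_tta(
    assembly: LegAssembly, config: RunConfig | None = None
) -> tuple[float, Direction]:
    """Tibial torsion: acute angle between the projections of the
    intermalleolar axis and the plateau central ML axis on the tibial axial
    plane."""
    config = config or RunConfig()
    angle, signed = _acute_axial_angle(
        assembly.ml_axes.proximal_tibial.direction,
        assembly.ml_axes.intermalleolar.direction,
        assembly.tibial_frame.axial_normal,
        assembly.side.sign,
    )
    direction = Direction.EXTERNAL if signed <= 0 else Direction.INTERNAL
    return angle, direction


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------


def _mesh_digest(model: LabeledBoneModel) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(model.mesh.vertices).tobytes())
    h.update(np.ascontiguousarray(model.mesh.faces).tobytes())
    for label in sorted(model.regions, key=lambda r: r.value):
        h.update(label.value.encode())
        h.update(np.ascontiguousarray(model.regions[label]).tobytes())
    return h.hexdigest()[:16]


def analyze_leg(
    femur: LabeledBoneModel,
    tibfib: LabeledBoneModel,
    config: RunConfig | None = None,
) -> AlignmentReport:
    """Full alignment pipeline: centres -> frames -> (virtual extension when
    configured and needed) -> joint orientations -> the eight angles."""
    config = config or RunConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except LegalignError as exc:
            raise StageError(name, exc) from exc

    assembly = stage("landmarks_frames", build_assembly, femur, tibfib, config)
    extension_meta = {"applied": False, "rotation_deg": 0.0}
    warning = None
    if assembly.extension_residual_deg > config.extension_auto_threshold_deg:
        if config.extension_policy == "strict":
            raise PrerequisiteError(
                "knee not extended (residual "
                f"{assembly.extension_residual_deg:.2f} deg) and "
                "extension.policy=strict",
                residual_deg=assembly.extension_residual_deg,
            )
        if config.extension_policy == "auto":
            assembly = stage("virtual_extension", virtual_extend, assembly, config)
            extension_meta = assembly.metadata.get("virtual_extension", extension_meta)
        else:  # ignore
            warning = (
                "extension prerequisite violated (residual "
                f"{assembly.extension_residual_deg:.2f} deg); coronal angles "
                "computed anyway per extension.policy=ignore"
            )
    orientations = stage("joint_orientations", joint_orientations, assembly, config)
    hkaa = stage(
        "hkaa",
        lambda: compute_hkaa(assembly, config)
        if config.extension_policy != "ignore"
        else _hkaa_unchecked(assembly),
    )
    mldfa = stage("mldfa", compute_mldfa, assembly, config, orientations)
    mmpta = stage("mmpta", compute_mmpta, assembly, config, orientations)
    mpdfa = stage("mpdfa", compute_mpdfa, assembly, config, orientations)
    mmppta, mlppta = stage("slopes", compute_slope_angles, assembly, config, orientations)
    fva, fva_dir = stage("fva", compute_fva, assembly, config)
    tta, tta_dir = stage("tta", compute_tta, assembly, config)

    residuals = dict(assembly.fit_residuals_mm)
    residuals["ptj_combined_plane_rms_mm"] = orientations.PTJ_combined.rms_mm
    residuals["ptj_medial_plane_rms_mm"] = orientations.PTJ_medial.rms_mm
    residuals["ptj_lateral_plane_rms_mm"] = orientations.PTJ_lateral.rms_mm

    metadata = {
        "tool": "legalign",
        "version": _version,
        "side": femur.side.value,
        "config_digest": config.digest(),
        "input_digests": {
            "femur": _mesh_digest(femur),
            "tibfib": _mesh_digest(tibfib),
        },
        "virtual_extension": {
            k: v
            for k, v in extension_meta.items()
            if k in ("applied", "rotation_deg", "residual_trajectory_deg")
        },
    }
    if warning:
        metadata["warning"] = warning

    return AlignmentReport(
        HKAA_deg=hkaa,
        mLDFA_deg=mldfa,
        mMPTA_deg=mmpta,
        mPDFA_deg=mpdfa,
        mMPPTA_deg=mmppta,
        mLPPTA_deg=mlppta,
        FVA_deg=fva,
        TTA_deg=tta,
        FVA_direction=fva_dir,
        TTA_direction=tta_dir,
        extension_residual_deg=assembly.extension_residual_deg,
        side=femur.side,
        fit_residuals_mm=residuals,
        metadata=metadata,
    )


def _hkaa_unchecked(assembly: LegAssembly) -> float:
    n = assembly.leg_frame.coronal_normal
    u = _project(assembly.axes.mFA.direction, n)
    v = _project(-assembly.axes.mTA.direction, n)
    theta = _ray_angle_deg(u, v)
    medial = _medial(assembly.leg_frame, assembly.side)
    return theta if float(np.dot(u + v, medial)) > 0 else 360.0 - theta
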