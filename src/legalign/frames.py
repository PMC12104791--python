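"""Anatomical coordinate systems and the knee-extension prerequisite.

Axis naming follows the consensus convention: the medial-lateral axis is x
and points to the patient's right, the posterior-anterior axis is y and
points anteriorly, the distal-proximal axis is z and points cranially.

* femoral frame — origin at the distal femoral joint centre; z along the
  mechanical femoral axis; x is the condylar central ML axis projected (along
  z) onto the femoral axial plane; y = z cross x.
* tibial/fibular frame — origin at the proximal tibial joint centre; z along
  the mechanical tibial axis; x from the plateau-centroid axis.
* leg frame — origin at the distal femoral joint centre; z along the
  mechanical leg axis (Mikulicz line, ankle to hip); x again from the
  condylar ML axis, so the leg frame's x never depends on tibial geometry.

Coronal angles are only meaningful with the knee extended: the mechanical
femoral and tibial axes must be parallel in the leg sagittal plane.
``virtual_extend`` realises that prerequisite by rigidly rotating the
tibia+fibula about the condylar cylinder axis (the only consensus-derived
medial-lateral knee axis) until the sagittal residual vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import RunConfig
from .errors import DegenerateGeometryError, ExtensionFailureError
from .geometry import Line3, rotation_about_axis, unit
from .landmarks import (
    CentralMLAxes,
    JointCenterSet,
    MechanicalAxes,
    derive_landmarks,
)
from .model import LabeledBoneModel

_ORTHO_TOL = 1e-9


@dataclass
class Frame:
    """Origin plus right-handed orthonormal (x right, y anterior, z cranial)."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.x, self.y, self.z = (
            np.asarray(self.x, dtype=float),
            np.asarray(self.y, dtype=float),
            np.asarray(self.z, dtype=float),
        )
        self.validate()

    def validate(self) -> None:
        for name in ("x", "y", "z"):
            if abs(np.linalg.norm(getattr(self, name)) - 1.0) > _ORTHO_TOL:
                raise DegenerateGeometryError(f"frame axis {name} is not unit-norm")
        for a, b in (("x", "y"), ("y", "z"), ("x", "z")):
            if abs(float(np.dot(getattr(self, a), getattr(self, b)))) > _ORTHO_TOL:
                raise DegenerateGeometryError(f"frame axes {a},{b} not orthogonal")
        if abs(float(np.dot(np.cross(self.x, self.y), self.z)) - 1.0) > _ORTHO_TOL:
            raise DegenerateGeometryError("frame is not right-handed")

    @property
    def axial_normal(self) -> np.ndarray:
        return self.z

    @property
    def coronal_normal(self) -> np.ndarray:
        return self.y

    @property
    def sagittal_normal(self) -> np.ndarray:
        return self.x


def _frame_from_z_and_ml(
    origin: np.ndarray,
    z_raw: np.ndarray,
    ml_raw: np.ndarray,
    config: RunConfig,
) -> Frame:
    """Shared construction: z along a mechanical axis (cranial), x from a
    medial-lateral axis projected along z, sign fixed to patient right."""
    z = unit(z_raw)
    if float(np.dot(z, config.hint_cranial)) < 0:
        z = -z
    ml = unit(ml_raw)
    # impossible-anatomy guard: ML axis must not be (near-)parallel to z
    if abs(float(np.dot(ml, z))) > np.cos(np.radians(0.1)):
        raise DegenerateGeometryError(
            "medial-lateral axis is parallel to the longitudinal axis; "
            "frame undefined"
        )
    x = ml - float(np.dot(ml, z)) * z
    x = unit(x)
    if float(np.dot(x, config.hint_right)) < 0:
        x = -x
    y = np.cross(z, x)
    y = y / np.linalg.norm(y)
    # re-orthogonalise x against accumulated rounding so the triad passes
    # the 1e-9 orthonormality contract exactly
    x = np.cross(y, z)
    x = x / np.linalg.norm(x)
    return Frame(origin, x, y, z)


def build_femoral_frame(
    centers: JointCenterSet,
    ml_axes: CentralMLAxes,
    config: RunConfig | None = None,
) -> Frame:
    config = config or RunConfig()
    mfa = centers.hip - centers.knee_femoral
    if np.linalg.norm(mfa) < config.min_mechanical_axis_mm:
        raise DegenerateGeometryError("mechanical femoral axis too short")
    return _frame_from_z_and_ml(
        centers.knee_femoral, mfa, ml_axes.distal_femoral.direction, config
    )


def build_tibial_frame(
    centers: JointCenterSet,
    ml_axes: CentralMLAxes,
    config: RunConfig | None = None,
) -> Frame:
    config = config or RunConfig()
    mta = centers.knee_tibial - centers.ankle
    if np.linalg.norm(mta) < config.min_mechanical_axis_mm:
        raise DegenerateGeometryError("mechanical tibial axis too short")
    return _frame_from_z_and_ml(
        centers.knee_tibial, mta, ml_axes.proximal_tibial.direction, config
    )


def build_leg_frame(
    centers: JointCenterSet,
    ml_axes: CentralMLAxes,
    config: RunConfig | None = None,
) -> Frame:
    """Leg frame: origin at the distal femoral joint centre, z along the
    Mikulicz line, x from the condylar ML axis (independent of the tibia)."""
    config = config or RunConfig()
    mla = centers.hip - centers.ankle
    if np.linalg.norm(mla) < config.min_leg_length_mm:
        raise DegenerateGeometryError(
            f"hip-ankle distance {np.linalg.norm(mla):.1f} mm below sanity "
            f"guard {config.min_leg_length_mm} mm"
        )
    return _frame_from_z_and_ml(
        centers.knee_femoral, mla, ml_axes.distal_femoral.direction, config
    )


@dataclass
class LegAssembly:
    """Both bone models with every derived frame, centre and axis."""

    femur: LabeledBoneModel
    tibfib: LabeledBoneModel
    centers: JointCenterSet
    axes: MechanicalAxes
    ml_axes: CentralMLAxes
    femoral_frame: Frame
    tibial_frame: Frame
    leg_frame: Frame
    extension_residual_deg: float
    fit_residuals_mm: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def side(self):
        return self.femur.side


def extension_residual(
    axes: MechanicalAxes, leg_frame: Frame
) -> float:
    """Absolute angle (degrees, [0, 90)) between the projections of the
    mechanical femoral and tibial axes onto the leg sagittal plane."""
    n = leg_frame.sagittal_normal
    f = axes.mFA.direction - float(np.dot(axes.mFA.direction, n)) * n
    t = axes.mTA.direction - float(np.dot(axes.mTA.direction, n)) * n
    nf, nt = np.linalg.norm(f), np.linalg.norm(t)
    if nf < 1e-9 or nt < 1e-9:
        raise DegenerateGeometryError("mechanical axis parallel to sagittal normal")
    cosang = abs(float(np.dot(f, t))) / (nf * nt)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def build_assembly(
    femur: LabeledBoneModel,
    tibfib: LabeledBoneModel,
    config: RunConfig | None = None,
) -> LegAssembly:
    """Derive landmarks and all three frames for a leg."""
    config = config or RunConfig()
    lm = derive_landmarks(femur, tibfib, config)
    femoral = build_femoral_frame(lm.centers, lm.ml_axes, config)
    tibial = build_tibial_frame(lm.centers, lm.ml_axes, config)
    leg = build_leg_frame(lm.centers, lm.ml_axes, config)
    residual = extension_residual(lm.axes, leg)
    return LegAssembly(
        femur=femur,
        tibfib=tibfib,
        centers=lm.centers,
        axes=lm.axes,
        ml_axes=lm.ml_axes,
        femoral_frame=femoral,
        tibial_frame=tibial,
        leg_frame=leg,
        extension_residual_deg=residual,
        fit_residuals_mm=dict(lm.fit_residuals_mm),
    )


def _signed_sagittal_angle(axes: MechanicalAxes, leg_frame: Frame) -> float:
    """Signed angle (radians) from projected mTA to projected mFA about the
    leg sagittal normal."""
    n = leg_frame.sagittal_normal
    f = axes.mFA.direction - float(np.dot(axes.mFA.direction, n)) * n
    t = axes.mTA.direction - float(np.dot(axes.mTA.direction, n)) * n
    f, t = unit(f), unit(t)
    return float(np.arctan2(float(np.dot(np.cross(t, f), n)), float(np.dot(t, f))))


def virtual_extend(
    assembly: LegAssembly, config: RunConfig | None = None
) -> LegAssembly:
    """Rigidly rotate the tibia+fibula about the condylar cylinder axis until
    the mechanical femoral and tibial axes are parallel in the leg sagittal
    plane.

    The ankle centre (and hence the leg frame) moves with the tibia, making
    the residual implicit; the construction therefore iterates
    rotate -> recompute tibial landmarks -> rebuild leg frame.  The femur is
    never moved.  Returns a new assembly with the net rigid transform recorded
    in ``metadata['virtual_extension']``.
    """
    config = config or RunConfig()
    tol = config.extension_tolerance_deg
    trajectory = [assembly.extension_residual_deg]
    if assembly.extension_residual_deg <= tol:
        meta = dict(assembly.metadata)
        meta["virtual_extension"] = {
            "applied": False,
            "rotation_deg": 0.0,
            "residual_trajectory_deg": trajectory,
        }
        return replace(assembly, metadata=meta)

    flexion_axis = assembly.ml_axes.distal_femoral  # fixed: femoral geometry
    tibfib = assembly.tibfib
    net_rotation = np.eye(3)
    net_translation = np.zeros(3)
    current = assembly
    total_angle = 0.0
    for _ in range(config.extension_max_iter):
        n = current.leg_frame.sagittal_normal
        axis_dir = flexion_axis.direction
        if float(np.dot(axis_dir, n)) < 0:
            axis_dir = -axis_dir
        angle = _signed_sagittal_angle(current.axes, current.leg_frame)
        rot = rotation_about_axis(axis_dir, angle)
        trans = flexion_axis.point - rot @ flexion_axis.point
        tibfib = tibfib.transformed(rot, trans)
        net_rotation = rot @ net_rotation
        net_translation = rot @ net_translation + trans
        total_angle += np.degrees(angle)
        current = build_assembly(assembly.femur, tibfib, config)
        trajectory.append(current.extension_residual_deg)
        if current.extension_residual_deg <= tol:
            break
    else:
        raise ExtensionFailureError(
            f"virtual extension did not reach {tol} deg in "
            f"{config.extension_max_iter} iterations",
            residual_trajectory_deg=trajectory,
        )
    meta = dict(current.metadata)
    meta["virtual_extension"] = {
        "applied": True,
        "rotation_deg": float(total_angle),
        "rotation_matrix": net_rotation.tolist(),
        "translation_mm": net_translation.tolist(),
        "residual_trajectory_deg": [float(r) for r in trajectory],
    }
    return replace(current, metadata=meta)
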