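"""Domain types: triangle meshes, articular-region labels, bone models and
the alignment report.

A :class:`LabeledBoneModel` is the unit of input for the whole pipeline: a
triangle surface mesh in millimetres (patient/scanner frame) plus named
articular-surface regions given as face-index sets.  The regions follow the
consensus subdivision of the articular surfaces: the distal femur splits into
medial condyle / lateral condyle / trochlea at the sulcus terminalis, and the
distal tibia/fibula into plafond / medial malleolus / lateral malleolus at the
medial gutter.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import InputValidationError, MissingRegionError

_DEGENERATE_AREA_MM2 = 1e-12


class Bone(enum.Enum):
    FEMUR = "FEMUR"
    TIBIA_FIBULA = "TIBIA_FIBULA"


class Side(enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"

    @property
    def sign(self) -> int:
        """+1 for RIGHT, -1 for LEFT.

        With the x-axis pointing to the patient's right, ``sign * x`` is the
        lateral direction and ``-sign * x`` the medial direction of this leg.
        """
        return 1 if self is Side.RIGHT else -1


class RegionLabel(enum.Enum):
    FEMORAL_HEAD = "FEMORAL_HEAD"
    FEMORAL_NECK = "FEMORAL_NECK"
    MEDIAL_FEMORAL_CONDYLE = "MEDIAL_FEMORAL_CONDYLE"
    LATERAL_FEMORAL_CONDYLE = "LATERAL_FEMORAL_CONDYLE"
    TROCHLEA = "TROCHLEA"
    MEDIAL_TIBIAL_PLATEAU = "MEDIAL_TIBIAL_PLATEAU"
    LATERAL_TIBIAL_PLATEAU = "LATERAL_TIBIAL_PLATEAU"
    TIBIAL_PLAFOND = "TIBIAL_PLAFOND"
    MEDIAL_MALLEOLUS_FACET = "MEDIAL_MALLEOLUS_FACET"
    LATERAL_MALLEOLUS_FACET = "LATERAL_MALLEOLUS_FACET"


FEMORAL_REGIONS = frozenset(
    {
        RegionLabel.FEMORAL_HEAD,
        RegionLabel.FEMORAL_NECK,
        RegionLabel.MEDIAL_FEMORAL_CONDYLE,
        RegionLabel.LATERAL_FEMORAL_CONDYLE,
        RegionLabel.TROCHLEA,
    }
)
TIBIAL_REGIONS = frozenset(
    {
        RegionLabel.MEDIAL_TIBIAL_PLATEAU,
        RegionLabel.LATERAL_TIBIAL_PLATEAU,
        RegionLabel.TIBIAL_PLAFOND,
        RegionLabel.MEDIAL_MALLEOLUS_FACET,
        RegionLabel.LATERAL_MALLEOLUS_FACET,
    }
)

#: regions that must be present for a full alignment analysis
REQUIRED_REGIONS = {
    Bone.FEMUR: FEMORAL_REGIONS,
    Bone.TIBIA_FIBULA: TIBIAL_REGIONS,
}


@dataclass
class TriangleMesh:
    """A plain triangle surface mesh (mm)."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3 or len(v) < 4:
            raise InputValidationError(
                f"mesh needs >= 4 vertices of dim 3, got shape {v.shape}"
            )
        if f.ndim != 2 or f.shape[1] != 3 or len(f) < 4:
            raise InputValidationError(
                f"mesh needs >= 4 triangular faces, got shape {f.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise InputValidationError("mesh contains non-finite coordinates")
        if f.min() < 0 or f.max() >= len(v):
            bad = int(np.argmax((f < 0).any(axis=1) | (f >= len(v)).any(axis=1)))
            raise InputValidationError(
                f"face {bad} has vertex index out of range [0, {len(v)})"
            )
        same = (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        )
        if same.any():
            raise InputValidationError(
                f"face {int(np.argmax(same))} repeats a vertex index"
            )
        areas = self.face_areas()
        if (areas <= _DEGENERATE_AREA_MM2).any():
            raise InputValidationError(
                f"face {int(np.argmax(areas <= _DEGENERATE_AREA_MM2))} is "
                "degenerate (area below tolerance)"
            )

    # -- geometry helpers ----------------------------------------------------

    def triangle_corners(self, face_indices=None) -> tuple:
        f = self.faces if face_indices is None else self.faces[face_indices]
        v = self.vertices
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def face_areas(self, face_indices=None) -> np.ndarray:
        a, b, c = self.triangle_corners(face_indices)
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def face_centroids(self, face_indices=None) -> np.ndarray:
        a, b, c = self.triangle_corners(face_indices)
        return (a + b + c) / 3.0

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        r = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return TriangleMesh(self.vertices @ r.T + t, self.faces.copy())


@dataclass
class LabeledBoneModel:
    """A bone mesh plus named articular-surface regions (face-index sets)."""

    bone: Bone
    side: Side
    mesh: TriangleMesh
    regions: dict  # RegionLabel -> np.ndarray of face indices

    def __post_init__(self) -> None:
        clean = {}
        for label, idx in self.regions.items():
            if not isinstance(label, RegionLabel):
                label = RegionLabel(str(label))
            clean[label] = np.unique(np.asarray(idx, dtype=np.int64))
        self.regions = clean
        self.validate()

    def validate(self, require_analysis_regions: bool = True) -> None:
        n_faces = len(self.mesh.faces)
        allowed = FEMORAL_REGIONS if self.bone is Bone.FEMUR else TIBIAL_REGIONS
        seen = np.zeros(n_faces, dtype=bool)
        for label, idx in self.regions.items():
            if label not in allowed:
                raise InputValidationError(
                    f"region {label.value} is not a {self.bone.value} region"
                )
            if len(idx) and (idx.min() < 0 or idx.max() >= n_faces):
                raise InputValidationError(
                    f"region {label.value} references face index outside "
                    f"[0, {n_faces})"
                )
            if seen[idx].any():
                raise InputValidationError(
                    f"region {label.value} overlaps another labeled region"
                )
            seen[idx] = True
        if require_analysis_regions:
            required = REQUIRED_REGIONS[self.bone]
            for label in (l for l in RegionLabel if l in required):
                if label not in self.regions or len(self.regions[label]) == 0:
                    raise MissingRegionError(
                        f"required region {label.value} missing"
                    )

    def region_faces(self, label: RegionLabel) -> np.ndarray:
        if label not in self.regions or len(self.regions[label]) == 0:
            raise MissingRegionError(f"required region {label.value} missing")
        return self.regions[label]

    def transformed(self, rotation, translation) -> "LabeledBoneModel":
        return LabeledBoneModel(
            bone=self.bone,
            side=self.side,
            mesh=self.mesh.transformed(rotation, translation),
            regions={k: v.copy() for k, v in self.regions.items()},
        )


class Direction(enum.Enum):
    """Direction labels for version/torsion."""

    ANTEVERSION = "ANTEVERSION"
    RETROVERSION = "RETROVERSION"
    EXTERNAL = "EXTERNAL"
    INTERNAL = "INTERNAL"


ANGLE_NAMES = (
    "HKAA_deg",
    "mLDFA_deg",
    "mMPTA_deg",
    "mPDFA_deg",
    "mMPPTA_deg",
    "mLPPTA_deg",
    "FVA_deg",
    "TTA_deg",
)


@dataclass
class AlignmentReport:
    """The eight consensus alignment angles plus diagnostics."""

    HKAA_deg: float
    mLDFA_deg: float
    mMPTA_deg: float
    mPDFA_deg: float
    mMPPTA_deg: float
    mLPPTA_deg: float
    FVA_deg: float
    TTA_deg: float
    FVA_direction: Direction
    TTA_direction: Direction
    extension_residual_deg: float
    side: Side
    fit_residuals_mm: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ANGLE_NAMES:
            value = float(getattr(self, name))
            if not np.isfinite(value):
                raise InputValidationError(f"{name} is not finite")
        if not 90.0 < self.HKAA_deg < 270.0:
            raise InputValidationError(f"HKAA {self.HKAA_deg} outside (90, 270)")
        for name in ("mLDFA_deg", "mMPTA_deg"):
            value = getattr(self, name)
            if not 45.0 < value < 135.0:
                raise InputValidationError(f"{name} {value} outside (45, 135)")
        for name in ("FVA_deg", "TTA_deg"):
            value = getattr(self, name)
            if not 0.0 <= value <= 90.0:
                raise InputValidationError(f"{name} {value} outside [0, 90]")
        if self.FVA_direction not in (Direction.ANTEVERSION, Direction.RETROVERSION):
            raise InputValidationError("FVA_direction must be ante/retroversion")
        if self.TTA_direction not in (Direction.EXTERNAL, Direction.INTERNAL):
            raise InputValidationError("TTA_direction must be external/internal")
        if self.extension_residual_deg < 0:
            raise InputValidationError("extension_residual_deg must be >= 0")

    def angles(self) -> dict:
        return {name: float(getattr(self, name)) for name in ANGLE_NAMES}
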