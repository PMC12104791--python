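"""Consensus joint centres and central medial-lateral axes.

Joint centres:

* hip — centre of a geometric sphere fit to all available femoral-head
  surface data;
* knee, femoral side — the condylar-cylinder axis is intersected with the
  femur and the midpoint of the two extreme intersections taken;
* knee, tibial side — midpoint of the two plateau area-weighted centroids;
* ankle — single area-weighted centroid of the pooled plafond and both
  malleolar articular facets (pooled, in contrast to the proximal tibia).

Central medial-lateral axes (used for frames, femoral version and tibial
torsion): the condylar cylinder axis (distal femur), the plateau-centroid
line (proximal tibia), the hip-centre-to-neck-centroid line, and the
intermalleolar centroid line.  Stored axes point from the medial to the
lateral structure; the side flag plus the caller's orientation hint resolve
that sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .errors import ConstructionError, DegenerateGeometryError
from .geometry import (
    CylinderFit,
    Line3,
    PointMode,
    SphereFit,
    fit_cylinder,
    fit_sphere,
    line_mesh_intersections,
    pooled_centroid,
    region_points,
    surface_centroid,
    unit,
)
from .model import Bone, LabeledBoneModel, RegionLabel


@dataclass
class JointCenterSet:
    hip: np.ndarray
    knee_femoral: np.ndarray
    knee_tibial: np.ndarray
    ankle: np.ndarray
    neck_center: np.ndarray

    def __post_init__(self) -> None:
        for name in ("hip", "knee_femoral", "knee_tibial", "ankle", "neck_center"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.linalg.norm(self.hip - self.knee_femoral) <= 0:
            raise DegenerateGeometryError("hip coincides with femoral knee centre")
        if np.linalg.norm(self.knee_tibial - self.ankle) <= 0:
            raise DegenerateGeometryError("tibial knee centre coincides with ankle")


@dataclass
class MechanicalAxes:
    """Mechanical femoral, tibial and leg (Mikulicz) axes.

    Directions are stored pointing proximally: mFA knee->hip, mTA ankle->knee,
    mLA ankle->hip.
    """

    mFA: Line3
    mTA: Line3
    mLA: Line3

    @classmethod
    def from_centers(cls, centers: JointCenterSet) -> "MechanicalAxes":
        return cls(
            mFA=Line3(centers.knee_femoral, centers.hip - centers.knee_femoral),
            mTA=Line3(centers.knee_tibial, centers.knee_tibial - centers.ankle),
            mLA=Line3(centers.ankle, centers.hip - centers.ankle),
        )


@dataclass
class CentralMLAxes:
    """Central medial-lateral axes, stored pointing medial -> lateral."""

    distal_femoral: Line3
    proximal_tibial: Line3
    neck_femur: Line3
    intermalleolar: Line3


def _oriented(line: Line3, lateral_hint: np.ndarray) -> Line3:
    """Flip a line's stored direction so it points toward the lateral side."""
    if float(np.dot(line.direction, lateral_hint)) < 0:
        return Line3(line.point, -line.direction)
    return line


def _lateral_hint(model: LabeledBoneModel, config: RunConfig) -> np.ndarray:
    return model.side.sign * config.hint_right


def hip_center(
    femur: LabeledBoneModel, config: RunConfig | None = None
) -> tuple[np.ndarray, SphereFit]:
    """Proximal femoral joint centre: sphere fit to the femoral head surface."""
    config = config or RunConfig()
    points, weights = region_points(
        femur, RegionLabel.FEMORAL_HEAD, PointMode.FACE_CENTROIDS
    )
    fit = fit_sphere(points, weights, tol=config.fit_tolerance, max_iter=config.fit_max_iter)
    return fit.center, fit


def condylar_cylinder(
    femur: LabeledBoneModel, config: RunConfig | None = None
) -> CylinderFit:
    """Cylinder fit to the pooled medial+lateral condylar articular surfaces."""
    config = config or RunConfig()
    pts, wts = [], []
    for region in (
        RegionLabel.MEDIAL_FEMORAL_CONDYLE,
        RegionLabel.LATERAL_FEMORAL_CONDYLE,
    ):
        p, w = region_points(femur, region, PointMode.FACE_CENTROIDS)
        pts.append(p)
        wts.append(w)
    return fit_cylinder(
        np.vstack(pts),
        np.concatenate(wts),
        tol=config.fit_tolerance,
        max_iter=config.fit_max_iter,
    )


def distal_femoral_center(
    femur: LabeledBoneModel,
    config: RunConfig | None = None,
    cylinder: CylinderFit | None = None,
) -> tuple[np.ndarray, CylinderFit]:
    """Distal femoral joint centre.

    The condylar-cylinder axis is intersected with the femur; the midpoint of
    the two extreme intersection points is the centre.  The intersection scope
    (whole bone vs condylar regions only) is configurable; whole bone is the
    default.
    """
    config = config or RunConfig()
    cylinder = cylinder or condylar_cylinder(femur, config)
    subset = None
    if config.femoral_intersection_scope == "condyle_regions":
        subset = np.concatenate(
            [
                femur.region_faces(RegionLabel.MEDIAL_FEMORAL_CONDYLE),
                femur.region_faces(RegionLabel.LATERAL_FEMORAL_CONDYLE),
            ]
        )
    hits = line_mesh_intersections(cylinder.axis, femur.mesh, subset)
    if len(hits) < 2:
        raise ConstructionError(
            f"condylar axis intersects the femur {len(hits)} time(s); "
            "need at least 2"
        )
    return 0.5 * (hits[0] + hits[-1]), cylinder


def proximal_tibial_center(tibfib: LabeledBoneModel) -> np.ndarray:
    """Midpoint of the two plateau area-weighted centroids."""
    medial = surface_centroid(tibfib, RegionLabel.MEDIAL_TIBIAL_PLATEAU)
    lateral = surface_centroid(tibfib, RegionLabel.LATERAL_TIBIAL_PLATEAU)
    return 0.5 * (medial + lateral)


def distal_tibfib_center(tibfib: LabeledBoneModel) -> np.ndarray:
    """Pooled area-weighted centroid of plafond + both malleolar facets."""
    return pooled_centroid(
        tibfib,
        (
            RegionLabel.TIBIAL_PLAFOND,
            RegionLabel.MEDIAL_MALLEOLUS_FACET,
            RegionLabel.LATERAL_MALLEOLUS_FACET,
        ),
    )


def neck_femur_axis(
    femur: LabeledBoneModel,
    config: RunConfig | None = None,
    hip: np.ndarray | None = None,
) -> tuple[Line3, np.ndarray]:
    """Line through the hip centre and the femoral-neck surface centroid.

    Returns the line (directed head -> neck, i.e. medial -> lateral) and the
    neck centroid.
    """
    config = config or RunConfig()
    if hip is None:
        hip, _ = hip_center(femur, config)
    neck = surface_centroid(femur, RegionLabel.FEMORAL_NECK)
    if np.linalg.norm(neck - hip) < 1.0:
        raise DegenerateGeometryError(
            "femoral neck centroid within 1 mm of the hip centre; "
            "neck-femur axis undefined"
        )
    return Line3(hip, neck - hip), neck


def central_ml_axis_distal_femur(
    femur: LabeledBoneModel,
    config: RunConfig | None = None,
    cylinder: CylinderFit | None = None,
) -> Line3:
    """Condylar cylinder axis, oriented medial -> lateral."""
    config = config or RunConfig()
    cylinder = cylinder or condylar_cylinder(femur, config)
    return _oriented(cylinder.axis, _lateral_hint(femur, config))


def central_ml_axis_proximal_tibia(
    tibfib: LabeledBoneModel, config: RunConfig | None = None
) -> Line3:
    """Line through the two plateau centroids, oriented medial -> lateral."""
    config = config or RunConfig()
    medial = surface_centroid(tibfib, RegionLabel.MEDIAL_TIBIAL_PLATEAU)
    lateral = surface_centroid(tibfib, RegionLabel.LATERAL_TIBIAL_PLATEAU)
    if np.linalg.norm(lateral - medial) < 1.0:
        raise DegenerateGeometryError("plateau centroids nearly coincide")
    return _oriented(Line3(medial, lateral - medial), _lateral_hint(tibfib, config))


def intermalleolar_axis(
    tibfib: LabeledBoneModel, config: RunConfig | None = None
) -> Line3:
    """Line through the malleolar facet centroids, oriented medial -> lateral."""
    config = config or RunConfig()
    medial = surface_centroid(tibfib, RegionLabel.MEDIAL_MALLEOLUS_FACET)
    lateral = surface_centroid(tibfib, RegionLabel.LATERAL_MALLEOLUS_FACET)
    if np.linalg.norm(lateral - medial) < 1.0:
        raise DegenerateGeometryError("malleolar centroids nearly coincide")
    return _oriented(Line3(medial, lateral - medial), _lateral_hint(tibfib, config))


@dataclass
class LandmarkResult:
    centers: JointCenterSet
    axes: MechanicalAxes
    ml_axes: CentralMLAxes
    fit_residuals_mm: dict = field(default_factory=dict)


def derive_landmarks(
    femur: LabeledBoneModel,
    tibfib: LabeledBoneModel,
    config: RunConfig | None = None,
) -> LandmarkResult:
    """Compute all joint centres, mechanical axes and central ML axes."""
    config = config or RunConfig()
    if femur.bone is not Bone.FEMUR or tibfib.bone is not Bone.TIBIA_FIBULA:
        raise ConstructionError("derive_landmarks needs a FEMUR and a TIBIA_FIBULA model")
    hip, sphere = hip_center(femur, config)
    cylinder = condylar_cylinder(femur, config)
    knee_f, _ = distal_femoral_center(femur, config, cylinder)
    knee_t = proximal_tibial_center(tibfib)
    ankle = distal_tibfib_center(tibfib)
    nfa, neck = neck_femur_axis(femur, config, hip=hip)
    centers = JointCenterSet(hip, knee_f, knee_t, ankle, neck)
    axes = MechanicalAxes.from_centers(centers)
    lateral_hint = _lateral_hint(femur, config)
    ml = CentralMLAxes(
        distal_femoral=_oriented(cylinder.axis, lateral_hint),
        proximal_tibial=central_ml_axis_proximal_tibia(tibfib, config),
        neck_femur=nfa,
        intermalleolar=intermalleolar_axis(tibfib, config),
    )
    residuals = {
        "femoral_head_sphere_rms_mm": sphere.rms_mm,
        "condylar_cylinder_rms_mm": cylinder.rms_mm,
    }
    return LandmarkResult(centers, axes, ml, residuals)
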