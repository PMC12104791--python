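"""Reading and writing bone models, region labels and alignment reports.

Meshes are STL (binary or ASCII) or PLY (binary little-endian or ASCII),
always in millimetres; units are never guessed — ``units.scale`` only
rescales explicitly.  Labels travel in a sidecar JSON file
(``legalign-labels-1``: region name -> 0-based face indices); a PLY mesh may
instead carry an integer ``region_id`` face property together with a small
JSON mapping table (``legalign-labels-plymap-1``).

Reports are written as JSON (``legalign-report-1``) or a one-row CSV twin.
"""

from __future__ import annotations

import csv
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import trimesh

from .errors import FormatError, InputValidationError
from .model import AlignmentReport, ANGLE_NAMES, Bone, Direction, LabeledBoneModel, RegionLabel, Side, TriangleMesh

LABEL_SCHEMA = "legalign-labels-1"
PLYMAP_SCHEMA = "legalign-labels-plymap-1"
REPORT_SCHEMA = "legalign-report-1"

_MESH_SUFFIXES = {".stl", ".ply"}


def merge_duplicate_vertices(
    vertices: np.ndarray, faces: np.ndarray, eps_mm: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``eps_mm`` (grid snap) and remap faces."""
    keys = np.round(vertices / eps_mm).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    return vertices[first], inverse[faces]


def _load_raw_mesh(path) -> trimesh.Trimesh:
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise FormatError(f"unsupported mesh format {path.suffix!r} (want .stl or .ply)")
    try:
        loaded = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - trimesh raises many types
        raise FormatError(f"could not read mesh {path}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise FormatError(f"{path} does not contain a triangle mesh")
    return loaded


def _ply_region_ids(mesh: trimesh.Trimesh, path) -> np.ndarray:
    raw = mesh.metadata.get("_ply_raw", {})
    face_data = raw.get("face", {}).get("data")
    try:
        ids = np.asarray(face_data["region_id"]).reshape(-1)
    except (TypeError, KeyError, IndexError, ValueError) as exc:
        raise FormatError(
            f"{path} has no integer 'region_id' face property required by the "
            f"{PLYMAP_SCHEMA} label dialect"
        ) from exc
    if len(ids) != len(mesh.faces):
        raise FormatError(f"{path}: region_id count does not match face count")
    return ids.astype(np.int64)


def _parse_region_name(name: str):
    try:
        return RegionLabel(name)
    except ValueError:
        raise InputValidationError(f"unknown region name: {name!r}") from None


def read_labels(label_path, mesh: trimesh.Trimesh | None = None, mesh_path=None) -> dict:
    """Read region labels from a sidecar JSON (either dialect)."""
    try:
        with open(label_path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"label file {label_path} is not valid JSON: {exc}") from exc
    schema = data.get("schema")
    if schema == LABEL_SCHEMA:
        regions = data.get("regions")
        if not isinstance(regions, dict):
            raise InputValidationError(f"{label_path}: 'regions' mapping missing")
        return {
            _parse_region_name(name): np.asarray(idx, dtype=np.int64)
            for name, idx in regions.items()
        }
    if schema == PLYMAP_SCHEMA:
        if mesh is None:
            raise InputValidationError(
                f"{label_path} uses the PLY face-property dialect but the mesh "
                "is not a PLY file"
            )
        mapping = data.get("region_ids")
        if not isinstance(mapping, dict):
            raise InputValidationError(f"{label_path}: 'region_ids' mapping missing")
        ids = _ply_region_ids(mesh, mesh_path)
        out = {}
        for name, rid in mapping.items():
            label = _parse_region_name(name)
            out[label] = np.flatnonzero(ids == int(rid)).astype(np.int64)
        return out
    raise FormatError(
        f"label file {label_path} has unknown schema {schema!r} "
        f"(want {LABEL_SCHEMA} or {PLYMAP_SCHEMA})"
    )


def read_bone_model(
    mesh_path,
    label_path,
    bone: Bone | str,
    side: Side | str,
    merge_eps_mm: float = 1e-6,
    units_scale: float = 1.0,
) -> LabeledBoneModel:
    """Load and validate a labeled bone model.

    Duplicate vertices within ``merge_eps_mm`` are merged and face indices
    remapped consistently (region labels index faces, whose order is stable
    under the merge).
    """
    bone = Bone(bone) if not isinstance(bone, Bone) else bone
    side = Side(side) if not isinstance(side, Side) else side
    raw = _load_raw_mesh(mesh_path)
    regions = read_labels(label_path, mesh=raw, mesh_path=mesh_path)
    vertices = np.asarray(raw.vertices, dtype=float) * float(units_scale)
    faces = np.asarray(raw.faces, dtype=np.int64)
    vertices, faces = merge_duplicate_vertices(vertices, faces, merge_eps_mm)
    mesh = TriangleMesh(vertices, faces)
    return LabeledBoneModel(bone=bone, side=side, mesh=mesh, regions=regions)


def write_labels(regions: dict, label_path) -> None:
    payload = {
        "schema": LABEL_SCHEMA,
        "regions": {
            label.value: np.asarray(idx, dtype=int).tolist()
            for label, idx in sorted(regions.items(), key=lambda kv: kv[0].value)
        },
    }
    with open(label_path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_bone_model(model: LabeledBoneModel, mesh_path, label_path=None) -> None:
    """Write a bone model mesh (format from extension) plus its label sidecar."""
    mesh_path = Path(mesh_path)
    tm = trimesh.Trimesh(
        vertices=model.mesh.vertices, faces=model.mesh.faces, process=False
    )
    if mesh_path.suffix.lower() not in _MESH_SUFFIXES:
        raise FormatError(f"unsupported mesh format {mesh_path.suffix!r}")
    tm.export(str(mesh_path))
    if label_path is not None:
        write_labels(model.regions, label_path)


def write_bone_model_ply_regions(model: LabeledBoneModel, mesh_path, label_path) -> None:
    """Write the model as ASCII PLY with a ``region_id`` face property and the
    matching mapping-table sidecar (the alternate label dialect)."""
    region_ids = np.zeros(len(model.mesh.faces), dtype=np.int64)
    mapping = {}
    for rid, (label, idx) in enumerate(
        sorted(model.regions.items(), key=lambda kv: kv[0].value), start=1
    ):
        region_ids[idx] = rid
        mapping[label.value] = rid
    with open(mesh_path, "w") as fh:
        v, f = model.mesh.vertices, model.mesh.faces
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(v)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {len(f)}\n")
        fh.write("property list uchar int vertex_indices\nproperty int region_id\n")
        fh.write("end_header\n")
        for p in v:
            fh.write(f"{p[0]:.9f} {p[1]:.9f} {p[2]:.9f}\n")
        for tri, rid in zip(f, region_ids):
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]} {rid}\n")
    with open(label_path, "w") as fh:
        json.dump({"schema": PLYMAP_SCHEMA, "region_ids": mapping}, fh, indent=1)


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

CSV_HEADER = [
    "side",
    *ANGLE_NAMES,
    "FVA_direction",
    "TTA_direction",
    "extension_residual_deg",
]


def report_payload(report: AlignmentReport, timestamp: str | None = None) -> dict:
    meta = dict(report.metadata)
    meta["timestamp"] = timestamp or datetime.now(timezone.utc).isoformat()
    return {
        "schema": REPORT_SCHEMA,
        "angles_deg": report.angles(),
        "directions": {
            "FVA": report.FVA_direction.value,
            "TTA": report.TTA_direction.value,
        },
        "extension_residual_deg": float(report.extension_residual_deg),
        "side": report.side.value,
        "fit_residuals_mm": {k: float(v) for k, v in report.fit_residuals_mm.items()},
        "metadata": meta,
    }


def write_report(report: AlignmentReport, path, format: str = "JSON") -> None:
    path = Path(path)
    fmt = format.upper()
    payload = report_payload(report)
    try:
        if fmt == "JSON":
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
        elif fmt == "CSV":
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(CSV_HEADER)
                writer.writerow(
                    [
                        report.side.value,
                        *(f"{getattr(report, name):.6f}" for name in ANGLE_NAMES),
                        report.FVA_direction.value,
                        report.TTA_direction.value,
                        f"{report.extension_residual_deg:.6f}",
                    ]
                )
        else:
            raise InputValidationError(f"unknown report format {format!r}")
    except OSError as exc:
        raise FormatError(f"cannot write report to {path}: {exc}") from exc


def read_report(path) -> AlignmentReport:
    """Read a JSON report back into an :class:`AlignmentReport`."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("schema") != REPORT_SCHEMA:
        raise FormatError(f"{path} is not a {REPORT_SCHEMA} file")
    angles = data["angles_deg"]
    return AlignmentReport(
        **{name: float(angles[name]) for name in ANGLE_NAMES},
        FVA_direction=Direction(data["directions"]["FVA"]),
        TTA_direction=Direction(data["directions"]["TTA"]),
        extension_residual_deg=float(data["extension_residual_deg"]),
        side=Side(data["side"]),
        fit_residuals_mm=data.get("fit_residuals_mm", {}),
        metadata=data.get("metadata", {}),
    )
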