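"""Run configuration.

All numeric tolerances and policy switches used by the pipeline live here with
their documented defaults.  Values can be overridden from a YAML file (dotted
keys, e.g. ``extension.tolerance_deg``) or programmatically; unknown keys are
rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import InputValidationError

#: default approximate patient directions of the scanner/emission frame:
#: rows are (right, anterior, cranial).
DEFAULT_ORIENTATION_HINT = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))


@dataclass
class RunConfig:
    """Pipeline configuration with stable, documented defaults."""

    # mesh handling
    mesh_merge_eps_mm: float = 1e-6
    units_scale: float = 1.0  # explicit rescale factor; never auto-detected

    # shape fitting
    fit_tolerance: float = 1e-10
    fit_max_iter: int = 200

    # distal femoral joint centre: intersect the condylar axis with the whole
    # bone (default) or with the condylar regions only
    femoral_intersection_scope: str = "bone"  # or "condyle_regions"

    # supracondylar plane: exact three-point construction (default) or a
    # least-squares plane over the top border band of each region
    sfj_mode: str = "three_point"  # or "border_band"
    sfj_border_band_fraction: float = 0.02

    # knee-extension prerequisite
    extension_tolerance_deg: float = 0.01
    extension_max_iter: int = 50
    extension_policy: str = "auto"  # "auto" | "strict" | "ignore"
    extension_auto_threshold_deg: float = 0.5

    # sanity guards
    min_mechanical_axis_mm: float = 10.0
    min_leg_length_mm: float = 100.0

    # approximate (right, anterior, cranial) directions of the input frame
    orientation_hint: tuple = DEFAULT_ORIENTATION_HINT

    def __post_init__(self) -> None:
        if self.extension_policy not in ("auto", "strict", "ignore"):
            raise InputValidationError(
                f"extension.policy must be auto|strict|ignore, got "
                f"{self.extension_policy!r}"
            )
        if self.femoral_intersection_scope not in ("bone", "condyle_regions"):
            raise InputValidationError(
                "center.femoral_intersection_scope must be 'bone' or "
                f"'condyle_regions', got {self.femoral_intersection_scope!r}"
            )
        if self.sfj_mode not in ("three_point", "border_band"):
            raise InputValidationError(
                f"sfj.mode must be three_point|border_band, got {self.sfj_mode!r}"
            )
        hint = np.asarray(self.orientation_hint, dtype=float)
        if hint.shape != (3, 3) or not np.all(np.isfinite(hint)):
            raise InputValidationError(
                "orientation.hint must be a finite 3x3 triple of directions"
            )
        if abs(np.linalg.det(hint)) < 1e-6:
            raise InputValidationError("orientation.hint directions are coplanar")

    # -- dotted-key mapping used by YAML files and the CLI ------------------

    _DOTTED = {
        "mesh.merge_eps_mm": "mesh_merge_eps_mm",
        "units.scale": "units_scale",
        "fit.tolerance": "fit_tolerance",
        "fit.max_iter": "fit_max_iter",
        "center.femoral_intersection_scope": "femoral_intersection_scope",
        "sfj.mode": "sfj_mode",
        "sfj.border_band_fraction": "sfj_border_band_fraction",
        "extension.tolerance_deg": "extension_tolerance_deg",
        "extension.max_iter": "extension_max_iter",
        "extension.policy": "extension_policy",
        "extension.auto_threshold_deg": "extension_auto_threshold_deg",
        "guards.min_mechanical_axis_mm": "min_mechanical_axis_mm",
        "guards.min_leg_length_mm": "min_leg_length_mm",
        "orientation.hint": "orientation_hint",
    }

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        """Build a config from a flat dotted-key mapping; unknown keys raise."""
        kwargs = {}
        for key, value in mapping.items():
            if key not in cls._DOTTED:
                raise InputValidationError(f"unknown config key: {key!r}")
            attr = cls._DOTTED[key]
            if attr == "orientation_hint":
                value = tuple(tuple(float(x) for x in row) for row in value)
            kwargs[attr] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputValidationError(f"config file {path} must be a mapping")
        return cls.from_mapping(data)

    def to_mapping(self) -> dict:
        inverse = {v: k for k, v in self._DOTTED.items()}
        out = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name == "orientation_hint":
                value = [list(row) for row in np.asarray(value, dtype=float)]
            out[inverse[f.name]] = value
        return out

    def digest(self) -> str:
        blob = json.dumps(self.to_mapping(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @property
    def hint_right(self) -> np.ndarray:
        return _unit(np.asarray(self.orientation_hint, dtype=float)[0])

    @property
    def hint_anterior(self) -> np.ndarray:
        return _unit(np.asarray(self.orientation_hint, dtype=float)[1])

    @property
    def hint_cranial(self) -> np.ndarray:
        return _unit(np.asarray(self.orientation_hint, dtype=float)[2])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)
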