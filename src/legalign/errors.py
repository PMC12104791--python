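"""Exception hierarchy.

Every failure mode raises a distinct subclass of :class:`LegalignError` so
callers (and the CLI exit-code mapping) can distinguish bad inputs from
geometric degeneracies and plain I/O trouble.
"""

from __future__ import annotations


class LegalignError(Exception):
    """Base class for all package errors."""


class InputValidationError(LegalignError):
    """Invalid mesh, labels, spec or configuration supplied by the caller."""


class MissingRegionError(InputValidationError):
    """A required articular region label is absent or empty."""


class FormatError(InputValidationError):
    """Unreadable or unsupported file format."""


class DegenerateGeometryError(LegalignError):
    """Input geometry does not determine the requested primitive
    (collinear points for a plane, coincident points for an axis, ...)."""


class FitFailureError(LegalignError):
    """Iterative shape fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConstructionError(LegalignError):
    """A consensus construction could not be completed on this geometry
    (e.g. the condylar axis misses the femur)."""


class PrerequisiteError(LegalignError):
    """The knee-extension prerequisite is violated beyond tolerance."""

    def __init__(self, message: str, residual_deg: float | None = None):
        super().__init__(message)
        self.residual_deg = residual_deg


class ExtensionFailureError(LegalignError):
    """Virtual extension did not converge; carries the residual trajectory."""

    def __init__(self, message: str, residual_trajectory_deg=()):
        super().__init__(message)
        self.residual_trajectory_deg = list(residual_trajectory_deg)


class StageError(LegalignError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause
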