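"""Exception hierarchy.

All package errors derive from :class:`RhinoflowError` so callers can catch
one base class; the leaves distinguish geometry, solver, and data problems.
"""


class RhinoflowError(Exception):
    """Base class for all rhinoflow errors."""


class InvalidGeometryError(RhinoflowError):
    """An airway model violates a structural invariant and cannot be solved."""


class DomainError(RhinoflowError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class ConvergenceError(RhinoflowError):
    """Iterative flow solve failed to reach the residual tolerance."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class CalibrationError(RhinoflowError):
    """Outlet-pressure calibration could not bracket the target flow."""


class TransportIntegrityError(RhinoflowError):
    """Transport integration produced a non-physical state (e.g. RH > 1)."""


class DegenerateDataError(RhinoflowError):
    """Statistical input carries no information (zero variance, empty group)."""


class ConfigError(RhinoflowError):
    """A configuration file is malformed or contains unknown keys."""


class CohortGenerationError(RhinoflowError):
    """A synthetic subject failed to generate; names the subject and stage."""

    def __init__(self, message, subject_index=None, stage=None):
        super().__init__(message)
        self.subject_index = subject_index
        self.stage = stage
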