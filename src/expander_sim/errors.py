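"""Exception hierarchy.

Every error raised by the package derives from :class:`ExpanderSimError`,
so callers (and the CLI) can separate configuration problems from runtime
failures with a single except clause.
"""


class ExpanderSimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ExpanderSimError):
    """Invalid configuration (geometry containment, schema, bad parameters)."""


class CalibrationError(ConfigurationError):
    """Invalid HU-density calibration table."""


class StructureError(ExpanderSimError):
    """A required structure mask is missing or inconsistent."""


class CorrectionError(ExpanderSimError):
    """Artefact correction cannot proceed (e.g. no artefact-free slice)."""


class DisplacementError(ExpanderSimError):
    """A port shift would leave the body (or the grid)."""

    def __init__(self, message: str, axis: str | None = None):
        super().__init__(message)
        self.axis = axis


class PlanError(ExpanderSimError):
    """Invalid beam/plan definition (empty PTV, zero-size aperture, ...)."""


class NormalizationError(PlanError):
    """Plan dose is zero inside the PTV; normalization impossible."""


class DistributionError(ConfigurationError):
    """Invalid error-distribution parameters."""


class ScenarioError(ExpanderSimError):
    """Scenario preconditions violated (tags, fraction counts, ...)."""


class StatisticsError(ExpanderSimError):
    """Statistics requested over an empty mask."""


class GeometryError(ExpanderSimError):
    """Grids/masks are not co-registered."""


class FormatError(ExpanderSimError):
    """A volume file is malformed or truncated."""
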