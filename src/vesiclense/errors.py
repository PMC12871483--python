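"""Exception hierarchy.

All package-specific errors derive from :class:`VesicleNSEError` so callers
can catch them with a single ``except``.  Domain violations on scalar inputs
additionally derive from ``ValueError``.
"""


class VesicleNSEError(Exception):
    """Base class for all vesiclense errors."""


class DomainError(VesicleNSEError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class InvalidGeometryError(DomainError):
    """Geometrically impossible vesicle (e.g. radius not larger than the
    membrane thickness)."""


class DegenerateSpectrumError(DomainError):
    """The mode cutoff leaves no undulation mode (l_max < 2)."""


class ConfigurationError(VesicleNSEError):
    """Inconsistent or unusable configuration (bad preset name, empty
    radius quadrature, unknown distribution family, ...)."""


class InsufficientDataError(VesicleNSEError):
    """Not enough data points for the requested operation."""


class NoRealSolutionError(DomainError):
    """An algebraic inversion has no real solution for the given inputs."""


class ParseError(VesicleNSEError):
    """A data file does not conform to the NSE TSV dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConvergenceError(VesicleNSEError):
    """An optimizer failed to converge."""
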