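"""Exception hierarchy.

Hard failures raise; recoverable per-position conditions (a normal that misses
the next front, an anchor too close to an endpoint) are signalled with NaN so
that callers can drop the position, mirroring how the measurement pipeline
treats unsampled positions.
"""


class FoldflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FoldflowError):
    """Invalid configuration or parameters (CLI exit code 2)."""


class GeometryError(FoldflowError):
    """Degenerate or invalid front geometry."""


class RegistrationError(FoldflowError):
    """Spatial/temporal registration cannot be performed."""


class SimulationError(FoldflowError):
    """Flow integration failed (e.g. stability bound violated)."""


class DataError(FoldflowError):
    """Malformed or insufficient input data (CLI exit code 3)."""


class InsufficientDataError(DataError):
    """Too few samples for the requested statistic."""
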