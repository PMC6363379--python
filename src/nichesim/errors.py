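"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, SchemaError -> 3,
everything else raised by the library -> 4.
"""


class NicheSimError(Exception):
    """Base class for all package errors."""


class ParameterError(NicheSimError, ValueError):
    """An invalid parameter value (out of range, inconsistent pairing)."""


class ConfigError(ParameterError):
    """An invalid configuration file (unknown key, unreadable, bad type)."""


class ContractViolationError(NicheSimError):
    """An operation was called on input its contract forbids."""


class DegenerateGeometryError(NicheSimError):
    """Geometry with no defined answer (e.g. a cell exactly at the tip centre)."""


class DegenerateScaleError(NicheSimError, ValueError):
    """Zero-spread input where a scale estimate is required."""


class SchemaError(NicheSimError, ValueError):
    """A tabular input does not match the expected column schema."""


class UnmatchedReferenceError(NicheSimError):
    """Manual reference positions that could not be matched to any spot."""

    def __init__(self, unmatched_indices, radius):
        self.unmatched_indices = list(unmatched_indices)
        self.radius = radius
        super().__init__(
            f"{len(self.unmatched_indices)} manual reference position(s) have no "
            f"unique automated spot within {radius} um: indices {self.unmatched_indices}"
        )


class CoverageError(NicheSimError):
    """A reference track does not span the time range of a cell track."""
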