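"""Exception hierarchy for glovescan."""


class GloveScanError(Exception):
    """Base class for all glovescan errors."""


class InvalidOrientationError(GloveScanError):
    """Quaternion is not a unit quaternion within tolerance."""


class DegenerateDirectionError(GloveScanError):
    """A point coincides with the spherical-coordinate origin (r = 0)."""


class NoReferenceError(GloveScanError):
    """No reference-sensor sample is available for time alignment."""


class ConfigurationError(GloveScanError):
    """A filter or simulator configuration value is infeasible."""


class EmptyInputError(GloveScanError):
    """An operation received an empty cloud or mesh it cannot handle."""


class AlignmentError(GloveScanError):
    """Ground-truth labels do not align one-to-one with raw samples."""


class SchemaError(GloveScanError):
    """A CSV file is missing a required column."""


class RowParseError(GloveScanError):
    """A CSV row contains a non-numeric cell; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line
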