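"""Exception hierarchy shared across the package."""


class StrainPSError(Exception):
    """Base class for all package errors."""


class ValidationError(StrainPSError):
    """Input violates an invariant of the internal data model."""


class FormatError(StrainPSError):
    """A file could not be parsed in its declared format."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ParameterError(StrainPSError):
    """A caller-supplied parameter is outside its admissible range."""


class DegenerateGroupingError(StrainPSError):
    """A grouping factor collapsed to fewer than two usable levels."""


class RareVariantError(StrainPSError):
    """Variant carried by too few strains for a population-structure test."""
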