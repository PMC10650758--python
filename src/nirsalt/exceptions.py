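"""Exception hierarchy.

``ValidationError`` covers anything the user can fix in their inputs or
configuration (exit code 1 at the CLI); everything else is a plain runtime
failure (exit code 2).
"""


class NirsaltError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NirsaltError, ValueError):
    """Invalid user input: malformed files, impossible configuration."""


class SpectraFormatError(ValidationError):
    """A spectra table violates the grid or layout contract."""


class ReferenceError_(ValidationError):
    """A reference-chemistry table violates its schema."""


class DataLeakageError(ValidationError):
    """Calibration and external-validation sample sets overlap."""
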