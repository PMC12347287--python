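"""Exception hierarchy shared across the package.

Validation problems (bad arguments, malformed files) derive from
:class:`ValidationError`; numerical fitting failures derive from
:class:`FitError`.  The CLI maps the former to exit code 2 and the
latter to exit code 3.
"""


class LipoCDError(Exception):
    """Base class for all package errors."""


class ValidationError(LipoCDError, ValueError):
    """Invalid input data or arguments."""


class DomainError(ValidationError):
    """Argument outside the mathematical domain of an operation."""


class SchemaError(ValidationError):
    """A delimited-text file does not match the expected schema."""


class FormatError(ValidationError):
    """A string (e.g. a molecular formula) cannot be parsed."""


class AssemblyError(ValidationError):
    """A report is missing required parts."""


class FitError(LipoCDError, RuntimeError):
    """A fit could not be performed or did not converge."""


class FlatSignalError(FitError):
    """Fluorescence signal carries no information (all values equal)."""


class NoMicellizationError(FitError):
    """No detectable break: post-micellar slope does not exceed baseline."""
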