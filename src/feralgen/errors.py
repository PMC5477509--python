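"""Exception hierarchy mapped to CLI exit codes.

Exit code 1: bad input (format, parameters, file contents).
Exit code 2: computation is degenerate (e.g. zero-variance Z-transform).
"""


class FeralgenError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(FeralgenError):
    """Malformed or inconsistent input data."""

    exit_code = 1


class FormatError(InputError):
    """A file does not conform to its declared format."""


class ParameterError(InputError):
    """An argument value is outside its admissible range."""


class DegenerateComputationError(FeralgenError):
    """A computation is undefined on the given data (e.g. zero variance)."""

    exit_code = 2
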