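"""Exception hierarchy.

Validation failures (bad inputs, schema violations) are distinguished from
computation failures (saturation, degenerate matrices) so the CLI can map
them to distinct exit codes.
"""


class BarcodekitError(Exception):
    """Base class for all package errors."""


class ValidationError(BarcodekitError):
    """Invalid input data or configuration."""


class ParseError(ValidationError):
    """Malformed input file; message names the file and, where known, the line."""


class ComputationError(BarcodekitError):
    """A numeric stage could not produce a defined result."""


class SaturationError(ComputationError):
    """K2P correction undefined: log argument non-positive (too divergent)."""
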