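"""Exception hierarchy used across the package."""


class HgfMetError(Exception):
    """Base class for package errors."""


class ConfigurationError(HgfMetError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(HgfMetError, ValueError):
    """Malformed input file (TSV/GMT/...)."""


class InputError(HgfMetError, ValueError):
    """Semantically invalid input to an operation."""


class DegenerateInputError(InputError):
    """Input that makes an operation undefined (constant vector, no events, ...)."""
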