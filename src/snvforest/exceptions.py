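"""Exception hierarchy shared across the package."""


class SnvForestError(Exception):
    """Base class for all package errors."""


class InputError(SnvForestError, ValueError):
    """Invalid user-supplied data (dimension mismatch, unknown id, ...)."""


class ConfigurationError(SnvForestError, ValueError):
    """Invalid configuration (degenerate bounds, bad hyperparameters, ...)."""


class DegenerateInputError(InputError):
    """Structurally valid input on which the operation is undefined."""


class ParseError(SnvForestError, ValueError):
    """Malformed input file; message names the offending file/line."""
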