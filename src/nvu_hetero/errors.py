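"""Exception hierarchy used across the pipeline."""


class NvuHeteroError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NvuHeteroError, ValueError):
    """An invalid simulation or pipeline configuration."""


class FormatError(NvuHeteroError, ValueError):
    """A malformed input file (MTX, TSV, GMT, ...)."""


class InputError(NvuHeteroError, ValueError):
    """Inputs that are well-formed but violate an operation's precondition."""
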