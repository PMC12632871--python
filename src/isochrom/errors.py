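"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI: ConfigError -> 2, DataError/ParseError -> 3.
"""


class IsochromError(Exception):
    """Base class for all package errors."""


class ConfigError(IsochromError):
    """Invalid configuration value or impossible requested geometry."""


class DataError(IsochromError):
    """Input data violates a documented contract (negative counts, shape mismatch...)."""


class ParseError(DataError):
    """A file could not be parsed; message names the offending line/cell."""
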