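"""Typed exceptions shared across the pipeline."""


class TroplipError(Exception):
    """Base class for all package errors."""


class ConfigError(TroplipError):
    """Invalid simulation or pipeline configuration."""


class FormatError(TroplipError):
    """Malformed or inconsistent on-disk input."""


class DataError(TroplipError):
    """Structurally valid input that violates an analysis precondition."""
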