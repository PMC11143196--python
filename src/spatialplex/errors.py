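"""Exception types shared across the pipeline."""


class SpatialplexError(Exception):
    """Base class for all package errors."""


class ConfigError(SpatialplexError):
    """Invalid configuration (bad parameters, missing paths, unknown names)."""


class DataError(SpatialplexError):
    """Malformed or inconsistent input data."""
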