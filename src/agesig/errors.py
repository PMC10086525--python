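"""Exception types shared across the package."""


class AgesigError(Exception):
    """Base class for all package errors."""


class ValidationError(AgesigError):
    """Malformed input data: readers reject rather than silently coerce."""


class ConfigError(AgesigError):
    """Invalid configuration value; the message names the offending field."""


class AnalysisError(AgesigError):
    """A computation cannot proceed (empty result, degenerate design, ...)."""
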