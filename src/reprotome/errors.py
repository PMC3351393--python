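"""Exception types shared across the pipeline."""


class ReprotomeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ReprotomeError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class NormalizationError(ReprotomeError, ValueError):
    """Array normalization failed; the message identifies the array."""


class ArgumentError(ReprotomeError, ValueError):
    """An operation received arguments outside its contract."""


class LookupMissingError(ReprotomeError, KeyError):
    """A requested gene/term is absent from the queried container."""


class StageError(ReprotomeError, RuntimeError):
    """A pipeline stage aborted; the message carries the stage name."""
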