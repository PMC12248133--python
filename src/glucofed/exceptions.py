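"""Exception types shared across the package."""


class GlucofedError(Exception):
    """Base class for all package errors."""


class ConfigError(GlucofedError, ValueError):
    """A configuration value violates an invariant; the message names the field."""


class ValidationError(GlucofedError, ValueError):
    """An input value (meal, scenario, action) is invalid."""


class NumericsError(GlucofedError, FloatingPointError):
    """A numeric quantity became non-finite; the message names the offending field."""


class EpisodeStateError(GlucofedError, RuntimeError):
    """The environment was used out of order (e.g. step after done)."""
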