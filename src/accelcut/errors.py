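"""Exception hierarchy shared across the package."""


class AccelcutError(Exception):
    """Base class for all package errors."""


class ParseError(AccelcutError):
    """A file could not be parsed; the message names the offending line."""


class ConfigError(AccelcutError):
    """Required configuration (e.g. sampling rate in a header) is missing."""


class ValidationError(AccelcutError):
    """Input violates a structural invariant (timing, overlap, class content)."""
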