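"""Exception types shared across the package."""


class VfcastError(Exception):
    """Base class for all package errors."""


class ConfigError(VfcastError):
    """A configuration field is invalid; the message names the field."""


class DataError(VfcastError):
    """Input records are malformed or violate a precondition."""


class FitError(VfcastError):
    """A model could not be estimated from the provided data."""
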