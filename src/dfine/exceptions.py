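"""Error types shared across the package."""


class InvalidModelError(ValueError):
    """Model parameters are structurally invalid (e.g. a covariance is not PSD)."""


class MissingComponentError(RuntimeError):
    """A requested optional component (e.g. the behaviour mapper) is absent."""


class DataError(ValueError):
    """Input data violates a contract (NaNs in observed entries, negative counts, ...)."""


class FormatError(ValueError):
    """A file does not follow the expected container layout."""
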