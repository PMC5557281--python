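"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class ConfigurationError(ValueError):
    """Raised when a configuration object or file is malformed."""
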