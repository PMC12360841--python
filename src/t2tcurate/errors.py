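"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when inputs or configuration violate a documented precondition."""


class ParseError(ValidationError):
    """Raised when an external file does not conform to its declared dialect."""
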