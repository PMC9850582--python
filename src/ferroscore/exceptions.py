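"""Exception hierarchy shared across the package."""


class FerroscoreError(Exception):
    """Base class for all errors raised by ferroscore."""


class FormatError(FerroscoreError):
    """A file does not conform to its declared on-disk dialect."""


class ValidationError(FerroscoreError):
    """Parsed content violates a domain invariant."""


class SchemaError(FerroscoreError):
    """A serialized model cannot be loaded (version mismatch, truncation)."""
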