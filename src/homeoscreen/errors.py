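"""Exception types shared across the pipeline."""


class HomeoscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HomeoscreenError, ValueError):
    """Invalid simulator / pipeline configuration; names the offending field."""


class SchemaError(HomeoscreenError, ValueError):
    """A table does not match its declared schema."""


class DomainError(HomeoscreenError, ValueError):
    """An operation was called outside its mathematical domain."""
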