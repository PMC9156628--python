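"""Exception types shared across the package."""


class HaploselError(Exception):
    """Base class for all package errors."""


class ValidationError(HaploselError):
    """An input object or file violates a format invariant."""


class ConfigurationError(HaploselError):
    """A configuration value is out of its valid range or inconsistent."""


class NotCodingError(HaploselError):
    """A variant position does not fall inside any CDS interval of a gene."""
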