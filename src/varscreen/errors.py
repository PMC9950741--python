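"""Exception hierarchy shared across the package."""


class VarscreenError(Exception):
    """Base class for all package-specific errors."""


class ParseError(VarscreenError):
    """A file could not be parsed (names the offending line where possible)."""


class SchemaError(VarscreenError):
    """A tabular input is missing a mandatory column or has the wrong layout."""


class ValidationError(VarscreenError):
    """Parsed values violate a domain invariant (duplicate keys, AF out of range, ...)."""
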