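"""Exception hierarchy shared across the package."""


class ItghError(Exception):
    """Base class for all package-raised errors."""


class ValidationError(ItghError):
    """A domain invariant was violated (bad field value, inconsistent table)."""


class FormatError(ItghError):
    """An input file does not conform to its declared format."""
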