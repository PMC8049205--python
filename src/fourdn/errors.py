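"""Exception hierarchy shared across the package."""


class FourDNError(Exception):
    """Base class for all package errors."""


class ValidationError(FourDNError):
    """Input violates a stated contract (bad metadata, duplicate keys, ...)."""


class FormatError(FourDNError):
    """A file on disk does not conform to the expected format."""


class AlignmentError(FourDNError):
    """Two objects that must share a bin index (or length) do not."""
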