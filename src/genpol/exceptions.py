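"""Exception hierarchy shared across the package."""


class GenpolError(Exception):
    """Base class for all genpol errors."""


class FormatError(GenpolError, ValueError):
    """A file on disk does not match its declared header / layout."""


class ValidationError(GenpolError, ValueError):
    """An in-memory object violates one of its invariants."""


class DomainError(GenpolError, ValueError):
    """An argument lies outside the mathematically admissible domain."""


class UnsupportedModeError(DomainError):
    """Transmit state with a = 0 or b = 0: the normalized two-channel
    backscatter vector E1/E2 is undefined there (pure H or pure V transmit
    divides by a vanishing amplitude)."""
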