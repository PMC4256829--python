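"""Exception hierarchy.

All fflrx-raised errors derive from :class:`FflrxError` so callers (and the
CLI) can distinguish input problems from genuine bugs.
"""


class FflrxError(Exception):
    """Base class for all errors raised by fflrx."""


class FormatError(FflrxError, ValueError):
    """An input file does not conform to its documented schema."""


class ValidationError(FflrxError, ValueError):
    """Input data violates a domain invariant (role conflict, bad edge, ...)."""


class DomainError(FflrxError, ValueError):
    """A quantity is undefined or out of its mathematical domain."""


class ConfigurationError(FflrxError, ValueError):
    """Mutually inconsistent or incomplete parameters."""
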