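"""Exception hierarchy for the screening workflow."""


class ToxscreenError(Exception):
    """Base class for all package errors."""


class ParseError(ToxscreenError, ValueError):
    """A file could not be parsed as the expected format."""


class UnsupportedDialectError(ParseError):
    """The file is a recognised format but an unsupported variant
    (e.g. profile-mode mzML; the workflow assumes centroided data)."""


class DomainError(ToxscreenError, ValueError):
    """An argument is outside its documented domain."""


class ConsistencyError(ToxscreenError, ValueError):
    """Data violates a structural invariant (e.g. precursor mismatch
    between a reference spectrum and its compound record)."""


class ContractViolation(ToxscreenError, ValueError):
    """An operation was called outside its documented contract."""
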