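"""Exception hierarchy for the tvcurve package."""


class TvCurveError(Exception):
    """Base class for all package errors."""


class ParseError(TvCurveError):
    """Raised when an input file or string cannot be parsed."""


class ValidationError(TvCurveError):
    """Raised when a parsed object violates a domain invariant."""


class BackendUnavailableError(TvCurveError):
    """Raised when a requested folding backend cannot be used on this host."""
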