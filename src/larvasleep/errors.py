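"""Exception hierarchy shared across the package."""


class LarvasleepError(Exception):
    """Base class for all package errors."""


class FormatError(LarvasleepError):
    """A delimited input file does not have the expected columns/layout."""


class StructuralError(LarvasleepError):
    """Input parses but violates a structural requirement (e.g. bin spacing)."""


class ValidationError(LarvasleepError):
    """Values violate a domain invariant (e.g. activity exceeding bin width)."""


class FitError(LarvasleepError):
    """A model fit failed to converge or was degenerate."""


class AnalysisError(LarvasleepError):
    """An analysis precondition was violated (windows, groups, coverage)."""
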