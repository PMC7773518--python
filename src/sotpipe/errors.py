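"""Exception hierarchy for sotpipe.

All package errors derive from :class:`SotPipeError` so callers can catch
one base class; the subclasses distinguish malformed files, invalid data,
and statistics that are undefined for the given input.
"""


class SotPipeError(Exception):
    """Base class for all sotpipe errors."""


class FormatError(SotPipeError):
    """A file or manifest does not follow the documented dialect."""


class SamplingError(SotPipeError):
    """Time stamps are not uniform at the declared tolerance, or conflict
    with a supplied sampling rate."""


class ValidationError(SotPipeError):
    """A domain object violates one of its invariants (non-finite sample,
    out-of-range height, EI outside [0, 100], ...)."""


class DegenerateInputError(SotPipeError):
    """Input is structurally valid but too small or too trivial for the
    requested computation (fewer than 2 samples, constant series, ...)."""


class DomainError(SotPipeError):
    """A quantity leaves the geometric model's domain, e.g. a COP excursion
    at least as large as the estimated COG height (arcsine undefined)."""


class InsufficientDataError(SotPipeError):
    """Too few paired observations for the requested statistic."""


class UndefinedStatisticError(SotPipeError):
    """The statistic does not exist for this input (zero variance)."""
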