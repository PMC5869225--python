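"""Exception hierarchy for the package.

Every error raised by the library derives from :class:`EDNADensityError`,
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class EDNADensityError(Exception):
    """Base class for all package errors."""


class DataFormatError(EDNADensityError):
    """Malformed input table: missing columns, duplicate rows, bad unit."""


class DataValidationError(EDNADensityError):
    """A value violates a domain invariant (negative concentration, etc.)."""


class UnknownSiteError(EDNADensityError):
    """A density record references a site absent from the eDNA table."""


class IdentifiabilityError(EDNADensityError):
    """The model cannot be identified from the data (e.g. no dual sites)."""


class DegenerateDataError(EDNADensityError):
    """Data carry no information about the calibration (all-zero dual sites)."""


class NotConvergedError(EDNADensityError):
    """An operation requires a converged fit but the fit did not converge."""
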