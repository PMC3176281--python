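"""Exception hierarchy.

All package-specific failures derive from :class:`RootkernError` so callers
can catch one base class at the CLI boundary.
"""


class RootkernError(Exception):
    """Base class for all rootkern errors."""


class ConfigurationError(RootkernError):
    """A configuration value (column mapping, kernel parameter set, fit
    option) is missing or inconsistent."""


class ValidationError(RootkernError):
    """Input rows violated an invariant.

    ``rows`` holds 1-based data-row numbers of the offending records when
    the error came from a table reader.
    """

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = tuple(rows) if rows is not None else ()


class ResolutionError(RootkernError):
    """A cross-reference (fragment -> core, species -> family) did not
    resolve."""


class DegeneratePointError(RootkernError):
    """Every source contributes zero mass at a requested point, so
    proportions are undefined there."""

    def __init__(self, message, point=None):
        super().__init__(message)
        self.point = point


class EdgeEffectError(RootkernError):
    """A point lies too close to the mapped boundary for unbiased
    proportions (unmapped outside stems could contribute)."""


class UndefinedValueError(RootkernError):
    """A statistic is undefined for the given data (e.g. zero total sum of
    squares)."""
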