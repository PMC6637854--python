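"""Exception hierarchy shared across the pipeline stages."""


class FvGapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FvGapError):
    """Invalid run or world configuration (bad bounds, missing fields)."""


class CalibrationError(FvGapError):
    """Base-year balances incompatible with the demand system."""


class ConvergenceError(FvGapError):
    """Market-clearing price could not be bracketed/solved within bounds."""

    def __init__(self, message, commodity=None, year=None, residual=None):
        super().__init__(message)
        self.commodity = commodity
        self.year = year
        self.residual = residual


class AlignmentError(FvGapError):
    """Two tables that must share keys do not."""

    def __init__(self, message, missing=None):
        super().__init__(message)
        self.missing = missing or []


class TaxonomyError(FvGapError):
    """Policy category absent from the shipped NOURISHING taxonomy."""


class MembershipError(FvGapError):
    """Bloc jurisdiction with no membership entry."""


class GroupingError(FvGapError):
    """Country without a region / group assignment."""


class DegeneratePopulationError(FvGapError):
    """Population pyramid sums to zero."""
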