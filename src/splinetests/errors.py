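"""Exception hierarchy shared by all splinetests modules."""


class SplineTestError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(SplineTestError):
    """A named column is absent from the input table."""


class EmptyInputError(SplineTestError):
    """No valid observations remain after parsing/dropping."""


class EmptyAfterFilterError(SplineTestError):
    """A prevalence filter removed every subject."""


class InconsistentGroupingError(SplineTestError):
    """A subject carries more than one group label."""


class SparseGroupError(SplineTestError):
    """A group has too few observations to support a spline fit."""


class NoOverlapError(SplineTestError):
    """Two curves share fewer than two grid points (disjoint x ranges)."""


class InsufficientDataError(SplineTestError):
    """Too few (distinct) points to fit the requested local polynomial."""
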