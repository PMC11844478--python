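"""Exception hierarchy.

Every error raised by the library derives from :class:`GenarcError` so that
callers (and the CLI) can catch pipeline failures in one place.
"""


class GenarcError(Exception):
    """Base class for all genarc errors."""


class InvalidSchemeError(GenarcError):
    """Bin widths are non-positive or do not sum to 100%."""


class DegenerateBinningError(GenarcError):
    """A bin received no members after assignment."""


class OrderingError(GenarcError):
    """Bin representative values are not strictly increasing."""


class EmptyInputError(GenarcError):
    """An operation received an empty record list."""


class InadmissibleRatioError(GenarcError):
    """|cor / dx| exceeds 1, outside the domain of acos."""


class DivergentDistanceError(GenarcError):
    """|angle| >= 90 degrees; the implied distance on y is unbounded."""


class TransformDomainError(GenarcError):
    """dx <= 0 or an evaluation point outside the curve domain."""


class InsufficientSupportError(GenarcError):
    """Too few distinct points or included pairs to fit the requested curve."""


class UnderdeterminedFitError(GenarcError):
    """The least-squares system is rank deficient beyond the intercept nullspace."""


class EmptyFitError(GenarcError):
    """Every distance estimate was excluded; nothing to fit."""


class MissingSEError(GenarcError):
    """A record scheduled for resampling has no finite standard error."""


class EnvelopeFailureError(GenarcError):
    """More than half of the envelope refits failed."""


class SchemaError(GenarcError):
    """An input table is missing a required column."""


class ParseError(GenarcError):
    """A table cell could not be parsed as a number."""


class ScenarioError(GenarcError):
    """A simulation scenario field is out of range."""
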