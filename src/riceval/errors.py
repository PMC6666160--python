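"""Exception hierarchy shared across the package."""

from .schema import SchemaError  # re-exported; raised by schema/table validation

__all__ = [
    "RicevalError",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "InsufficientDataError",
    "FixtureError",
    "ConsensusError",
]


class RicevalError(Exception):
    """Base class for package-specific failures."""


class ParseError(RicevalError):
    """A cell in a delimited input could not be parsed as a number."""

    def __init__(self, message: str, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class ValidationError(RicevalError, ValueError):
    """An input object violates a structural precondition."""


class InsufficientDataError(RicevalError, ValueError):
    """Too few observations for the requested statistic."""


class FixtureError(RicevalError, LookupError):
    """Unknown fixture identifier."""


class ConsensusError(RicevalError):
    """Factor and cluster partitions could not be reconciled.

    Carries the intermediate state (seed classes and attempted
    reassignments) for inspection.
    """

    def __init__(self, message: str, seeds=None, reassigned=None):
        super().__init__(message)
        self.seeds = seeds
        self.reassigned = reassigned
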