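"""Exception hierarchy for the reactionome pipeline.

Each error class maps to a distinct CLI exit code (see :mod:`reactionome.cli`),
so scripted callers can distinguish bad configuration from bad input data from
numerical failure.
"""


class ReactionomeError(Exception):
    """Base class for all package errors."""


class ConfigError(ReactionomeError):
    """Invalid run or simulation configuration."""


class InputError(ReactionomeError):
    """Missing or unreadable input file."""


class FormatError(ReactionomeError):
    """Input file present but malformed (bad header, cell, or duplicate id)."""


class ValidationError(ReactionomeError):
    """Input parsed but violates a domain invariant (off-grid temperature, …)."""


class ReconciliationError(ReactionomeError):
    """Expression matrix and sample metadata disagree about sample identity."""


class FitError(ReactionomeError):
    """Regression could not be fit (rank deficiency, too few observations)."""


class ContractError(ReactionomeError):
    """An operation was called outside its documented preconditions."""


class DegenerateDataError(ReactionomeError):
    """Statistic undefined for this input (zero margin, all-tied data, …)."""


class NumericalError(ReactionomeError):
    """A numerical routine failed beyond recoverable tolerance."""
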