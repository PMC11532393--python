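"""Exception hierarchy.

All errors raised by this package derive from :class:`StratarxError` so that
callers can catch package failures with a single except clause.  Subclasses
additionally derive from the closest builtin (``ValueError`` for contract
violations on values, ``RuntimeError`` for procedural failures) so generic
handling keeps working.
"""


class StratarxError(Exception):
    """Base class for all package errors."""


class SchemaError(StratarxError, ValueError):
    """A required column is missing or a declared covariate kind is invalid."""


class IntegrityError(StratarxError, ValueError):
    """Duplicate ids or structurally inconsistent records."""


class CohortValidationError(StratarxError, ValueError):
    """A cohort failed validation (missing values, empty cohort, ...)."""


class FittingError(StratarxError, RuntimeError):
    """A model could not be fitted (e.g. single-class training arm)."""


class MatchingError(StratarxError, RuntimeError):
    """Within-bucket matching is infeasible (e.g. an empty arm)."""


class PipelineError(StratarxError, RuntimeError):
    """An end-to-end pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


class GridExhaustedError(StratarxError, RuntimeError):
    """No weight on the search grid closed the confounding gap."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class InstanceTooLargeError(StratarxError, ValueError):
    """An exhaustive oracle was asked to handle an instance beyond its limits."""
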