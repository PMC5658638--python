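"""Exception hierarchy for the effort-risk pipeline.

Every error raised by the library derives from :class:`EffortRiskError`,
so callers (and the CLI) can catch one base class.
"""

from __future__ import annotations


class EffortRiskError(Exception):
    """Base class for all errors raised by effortrisk."""


class SchemaError(EffortRiskError):
    """An input table or config is missing a required column/key, or has
    an unknown one."""


class RowValidationError(EffortRiskError):
    """A row failed validation; carries the 1-based data row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class IntegrityError(EffortRiskError):
    """A cross-row invariant is violated (e.g. one member under two
    households); carries the offending identifiers."""

    def __init__(self, message: str, offenders: list | None = None):
        self.offenders = offenders or []
        super().__init__(message)


class WeightSumError(EffortRiskError):
    """The six factor weights do not sum to 100; carries the actual sum."""

    def __init__(self, actual_sum: float):
        self.actual_sum = actual_sum
        super().__init__(
            f"effort-factor weights must sum to 100%, got {actual_sum!r}"
        )


class EmptyInputError(EffortRiskError):
    """An operation that requires data received an empty collection."""


class ParameterError(EffortRiskError):
    """A parameter is outside its documented domain."""


class InsufficientDataError(EffortRiskError):
    """Too few observations for the requested statistic."""


class ConfigError(EffortRiskError):
    """A pipeline configuration is inconsistent."""


class PipelineStageError(EffortRiskError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
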