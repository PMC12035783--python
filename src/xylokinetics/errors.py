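"""Exception hierarchy shared across the pipeline.

Every reader/validator raises a subclass of :class:`XylokineticsError` with a
machine-readable ``category`` so callers (and tests) can dispatch on the kind
of failure rather than parse messages.
"""

from __future__ import annotations


class XylokineticsError(Exception):
    """Base class for all package errors."""

    category: str = "error"


class SchemaError(XylokineticsError):
    """A required column is missing or the table layout is wrong."""

    category = "schema"

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class RowError(XylokineticsError):
    """A row violates a type invariant (non-numeric area, bad sign, ...)."""

    category = "row"

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class InvariantError(XylokineticsError):
    """A structural invariant is violated (overlapping increments, gaps...)."""

    category = "invariant"


class ContiguityError(InvariantError):
    """A per-tree day series has a hole."""

    category = "contiguity"


class PreconditionError(XylokineticsError):
    """An operation was called with inputs outside its stated domain."""

    category = "precondition"


class ScheduleSpanError(XylokineticsError):
    """A generated treatment schedule does not fit in the experiment window."""

    category = "schedule_span"


class StageError(XylokineticsError):
    """Wraps a failure inside a named pipeline stage."""

    category = "stage"

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
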