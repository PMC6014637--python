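"""Typed errors raised by the elicitation pipeline.

Every malformed input produces one of these; data problems are never
silently dropped.
"""

from __future__ import annotations


class ElicitationError(Exception):
    """Base class for all package errors."""


class SchemaError(ElicitationError):
    """A required column or field is missing or of the wrong kind."""


class ValidationError(ElicitationError):
    """One or more records violate a dataset invariant.

    Parameters
    ----------
    message : str
        Human-readable summary.
    problems : list of str, optional
        One entry per offending record, each naming the row (1-based,
        excluding the header) and the violated invariant.
    """

    def __init__(self, message: str, problems: list[str] | None = None):
        self.problems = list(problems or [])
        if self.problems:
            message = message + "\n  " + "\n  ".join(self.problems)
        super().__init__(message)


class DomainError(ElicitationError, ValueError):
    """An operation was called with arguments outside its mathematical domain."""
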