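"""Exception hierarchy shared across the toolkit.

All errors raised deliberately by annokit derive from :class:`AnnokitError`
so callers (and the CLI) can distinguish user/input problems from genuine
bugs.
"""

from __future__ import annotations


class AnnokitError(Exception):
    """Base class for all errors raised by annokit."""


class InputError(AnnokitError):
    """A required input file is missing, unreadable, or empty."""


class SchemaError(AnnokitError):
    """An input table does not have the columns the caller mapped."""


class ParseError(AnnokitError):
    """A file could not be parsed; message includes the offending location."""


class ParameterError(AnnokitError):
    """A parameter value is outside its documented domain."""


class ConfigurationError(AnnokitError):
    """The configuration names an unknown backend, ontology, or option."""


class ValidationError(AnnokitError):
    """Data fails a semantic check (duplicate codes, unresolvable pairs)."""


class DuplicateCodeError(ValidationError):
    """Duplicate (ontology, code) pairs found within one release file."""

    def __init__(self, message: str, codes: list[str]):
        super().__init__(message)
        self.codes = codes


class NotFoundError(AnnokitError):
    """A lookup failed."""


class UnknownOntologyError(NotFoundError):
    """The requested ontology id has not been ingested."""


class TermNotFoundError(NotFoundError):
    """The ontology exists but does not contain the requested code."""


class EmptyOntologyError(AnnokitError):
    """An index was requested over an ontology with no terms."""


class SummaryError(AnnokitError):
    """Observations cannot be summarized as requested (e.g. nothing numeric)."""
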