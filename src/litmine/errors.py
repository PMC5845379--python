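"""Exception hierarchy shared across the package."""


class LitmineError(Exception):
    """Base class for all package errors."""


class InvalidInputError(LitmineError, ValueError):
    """An operation received input that violates its preconditions."""


class ValidationError(LitmineError, ValueError):
    """An annotation, document or record failed invariant checks."""


class NotFoundError(LitmineError, KeyError):
    """A requested document, category or record does not exist."""


class ParseError(LitmineError, ValueError):
    """A source file (XML, OBO, stored JSON) could not be parsed."""


class QuerySyntaxError(LitmineError, ValueError):
    """A query string violates the boolean query grammar."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class SchemaError(LitmineError, ValueError):
    """A curation form schema is malformed."""


class ExportError(LitmineError, ValueError):
    """A curation record cannot be exported."""
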