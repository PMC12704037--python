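"""Exception hierarchy.

Transport problems are kept distinct from "identifier not found" and from
backend-reported query syntax errors: the first is retryable, the second
is a data outcome (is_valid=False), the third implicates the query
builder rather than the network.
"""


class LitscreenError(Exception):
    """Base class for package errors."""


class TransportError(LitscreenError):
    """Network/HTTP failure after bounded retries; safe to retry later."""

    def __init__(self, message: str, *, query: str | None = None):
        super().__init__(message)
        self.query = query


class QuerySyntaxError(LitscreenError):
    """The backend rejected the query string itself."""


class VacuousQueryError(LitscreenError):
    """A valid candidate produced zero searchable terms."""


class ResolutionError(LitscreenError):
    """Identifier resolution failed in a non-retryable way (e.g. a
    secondary accession that only the identifier-mapping path handles)."""


class CorpusSpecError(LitscreenError):
    """A synthetic-corpus specification is unsatisfiable."""
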