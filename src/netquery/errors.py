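"""Exception and warning hierarchy shared across the package."""


class NetQueryError(Exception):
    """Base class for all netquery domain errors (CLI exit code 2)."""


class CXParseError(NetQueryError):
    """Malformed CX document; the message names the offending aspect."""


class ReferentialIntegrityError(NetQueryError):
    """A network violates its structural invariants (dangling edge
    endpoint, duplicate node identifier, ...)."""


class EmptyCollectionError(NetQueryError):
    """No gene set survived filtering; an index cannot be built."""


class EmptyQueryError(NetQueryError):
    """The query contained no tokens after splitting."""


class IndexFormatError(NetQueryError):
    """A serialized index file does not match the documented layout."""


class NetQueryWarning(UserWarning):
    """Base class for data-quality warnings."""


class QuerySizeWarning(NetQueryWarning):
    """Query exceeds the soft size limit; computation proceeds."""


class AmbiguousSymbolWarning(NetQueryWarning):
    """A symbol-table row conflicts with another and was dropped."""


class EmptyGeneSetWarning(NetQueryWarning):
    """A network reduced to zero recognizable genes and was excluded."""
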