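"""Exception hierarchy.

Errors are split by origin so the CLI can map them onto exit codes:
usage problems are handled by click itself, data-level problems raise
:class:`DataError` subclasses, and remote-transport problems raise
:class:`TransportError`.
"""


class LazySEError(Exception):
    """Base class for all package errors."""


class DataError(LazySEError):
    """A problem with user-supplied data, identifiers or schema."""


class ValidationError(DataError):
    """Container construction invariants violated (shapes, duplicate IDs)."""


class SelectorError(DataError):
    """A selector could not be resolved (unknown IDs, bad positions/mask)."""


class RegionParseError(DataError):
    """A region-of-interest string did not match ``seq:start-end[:strand]``."""


class SchemaError(DataError):
    """A relational source does not conform to the expected table layout."""


class TransportError(LazySEError):
    """Remote request failed after retries; carries the slab coordinates."""

    def __init__(self, message, slab=None, status=None):
        super().__init__(message)
        self.slab = slab
        self.status = status


class ProtocolError(LazySEError):
    """The remote service replied with a malformed or mismatched payload."""
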