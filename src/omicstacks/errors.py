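"""Exception hierarchy for omicstacks.

Every error raised by the public API derives from :class:`OmicstacksError`
so callers (and the CLI) can map failures to exit codes without string
matching.
"""


class OmicstacksError(Exception):
    """Base class for all omicstacks errors."""

    exit_code = 1


class ConfigurationError(OmicstacksError):
    """Invalid engine id, option value, or store/engine mismatch."""

    exit_code = 3


class StorageError(OmicstacksError):
    """The underlying database file is unreadable, corrupt, or unwritable."""

    exit_code = 4


class NotFoundError(OmicstacksError):
    """A table, layer, column or sample does not exist."""

    exit_code = 5


class SchemaError(OmicstacksError):
    """Schema invariant violation: duplicate/reserved names, kind mismatch."""

    exit_code = 6


class AppendError(OmicstacksError):
    """A row append failed; no partial write occurred."""

    exit_code = 7


class AlignmentError(OmicstacksError):
    """Column extension length does not match the stored row count."""

    exit_code = 8


class DuplicateError(OmicstacksError):
    """Table or layer already exists under a ``fail`` policy."""

    exit_code = 9


class QueryError(OmicstacksError):
    """Invalid row-value or position query (kind mismatch, empty set)."""

    exit_code = 10


class JoinError(OmicstacksError):
    """A join column is missing from one of the layers."""

    exit_code = 11


class ParseError(OmicstacksError):
    """Malformed VCF header; raised before any write."""

    exit_code = 12


class IngestError(OmicstacksError):
    """Malformed VCF data line; previously committed chunks are retained."""

    exit_code = 13


class SpecError(OmicstacksError):
    """Invalid synthetic-data generator specification."""

    exit_code = 14


class InsufficientDataError(OmicstacksError):
    """Too few observations for a regression fit."""

    exit_code = 15
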