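"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class RefstabError(Exception):
    """Base class for all package errors."""


class ConfigError(RefstabError):
    """Invalid configuration (bad enum value, malformed YAML, bad schema map)."""


class DataError(RefstabError):
    """Invalid or inconsistent input data."""


class SchemaError(DataError):
    """A mandatory column is missing or mis-typed in a delimited input table."""


class IntegrityError(DataError):
    """Duplicate keys or violated uniqueness constraints in input data."""


class InsufficientDataError(DataError):
    """Too few genes, samples, or replicates for the requested statistic."""


class DomainError(DataError):
    """A numeric value lies outside its mathematical domain (e.g. RQ <= 0)."""
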