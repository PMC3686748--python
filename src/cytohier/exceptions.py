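"""Exception hierarchy shared across the package."""


class CytohierError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CytohierError):
    """A required column is missing or a column map is malformed."""


class DataValidationError(CytohierError):
    """A row carries an unknown label or an unparseable value."""


class DomainError(CytohierError, ValueError):
    """An argument lies outside its mathematical domain (e.g. LOD <= 0)."""


class StateError(CytohierError, RuntimeError):
    """An operation was applied to an object in the wrong state."""


class ConfigError(CytohierError):
    """A chain or simulation configuration is invalid."""


class OracleSizeError(CytohierError):
    """A brute-force oracle was asked to handle an instance it cannot."""


class OrientationError(DomainError):
    """A fold change was passed with the wrong reference orientation."""
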