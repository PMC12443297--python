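"""Exception hierarchy shared across the package."""


class SpatialAccessError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SpatialAccessError, ValueError):
    """A configuration object violates its invariants; names the field."""


class SchemaError(SpatialAccessError, ValueError):
    """An input table is missing required columns or contains invalid values."""


class IntegrityError(SpatialAccessError, ValueError):
    """Cross-object identifiers disagree (matrix vs tables, surface vs surface)."""
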