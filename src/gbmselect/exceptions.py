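"""Exception types raised across the package."""


class GbmSelectError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GbmSelectError, ValueError):
    """An argument or configuration value violates its contract."""


class SchemaError(GbmSelectError, ValueError):
    """An input table is missing mandatory columns."""
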