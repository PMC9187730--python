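"""Exception hierarchy shared across the pipeline stages."""


class CatPainError(Exception):
    """Base class for all package errors."""


class SchemaError(CatPainError):
    """A table is missing required columns or carries unexpected ones."""


class ParseError(CatPainError):
    """A cell could not be parsed (carries the offending row index)."""


class ValidationError(CatPainError):
    """A domain invariant is violated (duplicate IDs, bad enum value...)."""


class DegenerateGeometryError(CatPainError):
    """Geometry leaves a transform undefined (e.g. coincident eye centers)."""


class ConfigurationError(CatPainError):
    """A configuration value is unusable for the requested operation."""
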