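"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


class SchemaError(ValueError):
    """A table is missing required columns or has the wrong dtypes."""


class GeometryError(ValueError):
    """A geometric object is degenerate (e.g. a section plane with collinear axes)."""


class ConfigError(ValueError):
    """A configuration value is inconsistent or missing."""
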