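"""Exception hierarchy shared across the package."""


class DelfiTFError(Exception):
    """Base class for all package-specific errors."""


class TilingError(DelfiTFError):
    """Reference tiling construction or validation failed."""


class ParseError(DelfiTFError):
    """A text input (BED, TSV) could not be parsed."""


class SampleQCError(DelfiTFError):
    """A sample failed a quality gate (e.g. too many missing ratio groups)."""


class PanelError(DelfiTFError):
    """Healthy-panel reference statistics are invalid or insufficient."""


class ModelError(DelfiTFError):
    """Model training, scoring, or version-compatibility failure."""
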