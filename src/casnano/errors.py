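"""Exception hierarchy shared across the package."""


class CasnanoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CasnanoError):
    """Invalid configuration value (counts, thresholds, paths)."""


class ParseError(CasnanoError):
    """Malformed structure file, identifier, descriptor table or feature name."""


class StructureError(CasnanoError):
    """Geometric operation called with inconsistent structural input."""


class DataError(CasnanoError):
    """Dataset assembly or annotation inconsistency."""


class PipelineError(CasnanoError):
    """Model training / selection / evaluation contract violation."""
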