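"""Exception hierarchy shared across the pipeline stages."""


class FwhmVascError(Exception):
    """Base class for all package errors."""


class ValidationError(FwhmVascError, ValueError):
    """A parameter or data structure violates its documented contract."""


class ConfigurationError(FwhmVascError, ValueError):
    """A phantom or run configuration is internally inconsistent."""


class GeometryError(FwhmVascError, ValueError):
    """A point, line or ROI falls outside the volume or is degenerate."""


class FormatError(FwhmVascError, ValueError):
    """An input file does not have the expected structure."""


class AnalysisError(FwhmVascError, RuntimeError):
    """The data do not support the requested measurement."""


class ReconstructionError(FwhmVascError, RuntimeError):
    """No confusion matrix is consistent with the printed intervals."""
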