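"""Exception types shared across the pipeline."""


class SedScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SedScreenError):
    """Invalid study design or run configuration."""


class DegenerateControlError(SedScreenError):
    """Vehicle-control statistics unusable (e.g. zero mean)."""


class InsufficientDataError(SedScreenError):
    """Too few samples/wells/dilutions for the requested operation."""


class ZeroVarianceError(SedScreenError):
    """A statistic is undefined because an input has no variance."""


class PipelineError(SedScreenError):
    """A pipeline stage output is missing or inconsistent."""
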