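"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`GazekitError` so callers (and the
CLI) can distinguish user/configuration problems from genuine bugs.
"""


class GazekitError(Exception):
    """Base class for all errors raised by gazekit."""


class ConfigurationError(GazekitError):
    """Invalid simulation, detection, or run configuration."""


class SchemaError(GazekitError):
    """An input table is missing required columns or tracked points."""


class ParseError(GazekitError):
    """A cell in an input file could not be parsed."""


class TimingError(GazekitError):
    """Sample timing is inconsistent with the declared rate."""


class QualityError(GazekitError):
    """Too much of a trace failed quality control to analyze."""


class CalibrationError(GazekitError):
    """Tracked displacement outside the arcsine domain of the calibration."""


class AlignmentError(GazekitError):
    """Two traces that must share a clock do not."""


class DegenerateSignalError(GazekitError):
    """A signal with zero variance cannot be standardized or regressed."""


class WindowError(GazekitError):
    """A trace does not cover the analysis window around an event."""


class InsufficientDataError(GazekitError):
    """Too few observations for the requested statistic."""


class GenerationError(GazekitError):
    """The synthetic generator was asked for something it cannot emit."""


class ReportError(GazekitError):
    """A report was requested from an incomplete run directory."""


class PipelineError(GazekitError):
    """Wraps a stage failure with the stage name for CLI reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
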