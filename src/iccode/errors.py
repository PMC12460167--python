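"""Exception hierarchy for iccode."""


class ICCodeError(Exception):
    """Base class for all package errors."""


class CalibrationError(ICCodeError):
    """Raised when a waveform cannot be calibrated (e.g. all-zero input)."""


class StimulusError(ICCodeError):
    """Invalid stimulus-synthesis parameters (ramp too long, band above Nyquist, ...)."""


class ShapeError(ICCodeError):
    """Array shape/alignment violation at a module boundary."""


class PreprocError(ICCodeError):
    """Invalid input to neural preprocessing (constant trace, missing trials, ...)."""


class MetricError(ICCodeError):
    """Metric undefined for the given inputs (non-positive denominator, empty data)."""


class TrainingError(ICCodeError):
    """Training diverged or was mis-configured."""
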