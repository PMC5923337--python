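"""Exception hierarchy for sensor-model and estimation failures.

All errors derive from :class:`AdlayerError` so callers can catch the
package's failures with a single ``except`` clause; the finer classes map
onto distinct physical or numerical failure modes (bad calibration,
saturated response, ill-conditioned noise, unusable input files).
"""


class AdlayerError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(AdlayerError, ValueError):
    """A physical parameter violates its constraint (e.g. l_d <= 0)."""


class CalibrationError(AdlayerError, ValueError):
    """A calibration quantity is unusable (zero bulk sensitivity,
    zero saturation shift, rank-deficient calibration series)."""


class SaturationError(AdlayerError, ValueError):
    """A resonance shift is at or beyond the saturation shift
    Δλ_max, where the log-linearisation is undefined."""


class IllConditionedError(AdlayerError, ValueError):
    """A covariance or sensitivity matrix is singular or too badly
    conditioned for a reliable solve."""


class UnidentifiableError(AdlayerError, ValueError):
    """The requested quantity is not identifiable from the data
    (e.g. a bulk-RI change with a zero-thickness adlayer)."""


class InsufficientDataError(AdlayerError, ValueError):
    """Too few observations for the requested statistic."""


class TrackingError(AdlayerError, ValueError):
    """Resonance tracking failed inside the requested window."""


class ParseError(AdlayerError, ValueError):
    """A delimited text input could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
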