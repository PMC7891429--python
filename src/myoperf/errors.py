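"""Exception hierarchy for the perfusion pipeline.

Errors are grouped so a CLI can map them onto distinct exit codes:
input/contract problems, calibration failures, geometry failures, and
configuration (pathological-parameter) failures.
"""


class MyoperfError(Exception):
    """Base class for all package errors."""


class InputError(MyoperfError, ValueError):
    """Invalid or inconsistent user input (masks, curves, shapes)."""


class DomainError(MyoperfError, ValueError):
    """Argument outside the physical domain of a model (e.g. T1 <= 0)."""


class CalibrationError(MyoperfError, ValueError):
    """Baseline signal unusable for scaling-factor estimation."""


class GeometryError(MyoperfError, ValueError):
    """Contours are degenerate, crossing, or inconsistent with the image."""


class ConfigurationError(MyoperfError, ValueError):
    """Parameters make the model pathological (e.g. non-monotone signal)."""


class FlatCurveError(InputError):
    """No contrast arrival could be detected on a curve."""


class InsufficientBaselineError(InputError):
    """Too few pre-contrast frames to form a baseline estimate."""
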