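"""Dynamic-series containers, AIF extraction and first-pass delineation.

The arterial input function (AIF) is the mean signal of a region of
interest in the left-ventricular blood pool.  Contrast arrival is detected
on the AIF with a baseline-relative threshold; the pre-arrival baseline is
the temporal median; and the end of the first pass is the valley after the
AIF maximum, before recirculation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .errors import FlatCurveError, InputError, InsufficientBaselineError

__all__ = [
    "DCESeries",
    "ConcentrationCurve",
    "extract_aif",
    "detect_arrival",
    "compute_baseline",
    "truncate_first_pass",
    "resample_uniform",
]


@dataclass
class DCESeries:
    """A dynamic contrast-enhanced image time series (one slice).

    Attributes
    ----------
    frames : ndarray, shape (T, R, C)
        Signal stack, one 2D frame per timepoint.
    frame_times : ndarray, shape (T,)
        Acquisition time of each frame, seconds; strictly increasing.
    cardiac_phase : str
        ``"systole"`` or ``"diastole"``.
    pixel_spacing : tuple of float
        (row, col) spacing in mm.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    cardiac_phase: str = "diastole"
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise InputError("frames must be a (T, R, C) stack")
        if self.frame_times.shape != (self.frames.shape[0],):
            raise InputError("frame_times length must match number of frames")
        if self.frames.shape[0] < 10:
            raise InputError("a DCE series needs at least 10 frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise InputError("frame_times must be strictly increasing")
        if self.cardiac_phase not in ("systole", "diastole"):
            raise InputError(f"unknown cardiac phase {self.cardiac_phase!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ConcentrationCurve:
    """A time-resolved curve: AIF or tissue, in signal units or mmol/L."""

    times: np.ndarray
    values: np.ndarray
    arrival_index: int | None = None
    first_pass_end_index: int | None = None
    units: str = "signal"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InputError("times and values must be 1D of equal length")
        if self.arrival_index is not None and self.first_pass_end_index is not None:
            n = len(self.values)
            if not 0 <= self.arrival_index < self.first_pass_end_index < n:
                raise InputError(
                    "need 0 <= arrival_index < first_pass_end_index < length"
                )

    def __len__(self) -> int:
        return len(self.values)

    def first_pass_window(self) -> slice:
        if self.arrival_index is None or self.first_pass_end_index is None:
            raise InputError("arrival/first-pass indices not set")
        return slice(self.arrival_index, self.first_pass_end_index + 1)


def extract_aif(series: DCESeries, blood_roi: np.ndarray) -> ConcentrationCurve:
    """Mean signal over the LV blood-pool ROI, per frame.

    The ROI is a boolean mask drawn on one frame with good blood/myocardium
    contrast (manual in practice; provided by the phantom here).
    """
    blood_roi = np.asarray(blood_roi, dtype=bool)
    if blood_roi.shape != series.shape:
        raise InputError("blood ROI shape must match the image shape")
    if not blood_roi.any():
        raise InputError("blood ROI is empty")
    values = series.frames[:, blood_roi].mean(axis=1)
    return ConcentrationCurve(series.frame_times.copy(), values, units="signal")


def detect_arrival(
    curve: ConcentrationCurve | np.ndarray,
    k: float = 5.0,
    n_consecutive: int = 2,
    min_baseline: int = 5,
) -> int:
    """Detect the contrast-arrival frame on a curve.

    Returns the first index whose value (and the next ``n_consecutive - 1``
    values) exceeds ``median + k * SD`` of all earlier frames, scanning from
    ``min_baseline`` onward.  All earlier frames define the baseline window.
    A tiny relative floor keeps the threshold meaningful on noiseless data
    where the baseline SD is exactly zero.

    Raises
    ------
    FlatCurveError
        If no frame exceeds the threshold.
    """
    values = curve.values if isinstance(curve, ConcentrationCurve) else np.asarray(curve, float)
    n = len(values)
    if n < min_baseline + n_consecutive:
        raise InputError("curve too short for arrival detection")
    for i in range(min_baseline, n - n_consecutive + 1):
        base = values[:i]
        med = np.median(base)
        sd = base.std()
        thr = med + max(k * sd, 1e-9 * max(abs(med), 1.0))
        if np.all(values[i : i + n_consecutive] > thr):
            return i
    raise FlatCurveError("no contrast arrival detected (flat curve?)")


def compute_baseline(curve: ConcentrationCurve | np.ndarray, arrival_index: int) -> float:
    """Pre-contrast baseline: temporal median from start to arrival."""
    values = curve.values if isinstance(curve, ConcentrationCurve) else np.asarray(curve, float)
    if arrival_index < 3:
        raise InsufficientBaselineError(
            f"need >= 3 pre-contrast frames, got {arrival_index}"
        )
    return float(np.median(values[:arrival_index]))


def truncate_first_pass(
    curve: ConcentrationCurve | np.ndarray,
    arrival_index: int | None = None,
    smooth_size: int = 3,
) -> int:
    """Locate the end of the first pass: the valley after the AIF maximum.

    A moving-median smoothing (default 3 frames) suppresses noise minima
    before the turning point is searched; the returned index refers to the
    unsmoothed curve (argmin of the raw curve between the peak and the
    smoothed turning point).  Falls back to the last frame, with a warning,
    when no recirculation upturn exists.
    """
    if isinstance(curve, ConcentrationCurve):
        values = curve.values
        if arrival_index is None:
            arrival_index = curve.arrival_index or 0
    else:
        values = np.asarray(curve, dtype=float)
        arrival_index = arrival_index or 0
    n = len(values)
    peak = arrival_index + int(np.argmax(values[arrival_index:]))
    if peak >= n - 1:
        warnings.warn("AIF peaks at the last frame; no valley found", RuntimeWarning)
        return n - 1
    smooth = median_filter(values, size=smooth_size, mode="nearest")
    turn = None
    for i in range(peak + 1, n - 1):
        if smooth[i + 1] > smooth[i]:
            turn = i
            break
    if turn is None:
        warnings.warn(
            "no valley before end of series; using the last frame", RuntimeWarning
        )
        turn = n - 1
    valley = peak + 1 + int(np.argmin(values[peak + 1 : turn + 1]))
    return valley


def resample_uniform(
    times: np.ndarray, values: np.ndarray, dt: float | None = None, rtol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a curve onto a uniform grid by linear interpolation.

    Deconvolution assumes uniform sampling; ECG-gated frames are nearly
    uniform at rest, so the default target spacing is the median inter-frame
    interval.  Curves that are already uniform are returned unchanged.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    diffs = np.diff(times)
    if dt is None:
        dt = float(np.median(diffs))
    if np.allclose(diffs, dt, rtol=rtol, atol=1e-12):
        return times, values
    new_times = np.arange(times[0], times[-1] + 0.5 * dt, dt)
    return new_times, np.interp(new_times, times, values)
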