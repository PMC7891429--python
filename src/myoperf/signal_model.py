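"""Saturation-recovery FLASH signal model and relaxivity conversion.

The DCE readout is a single-shot saturation-recovery FLASH (SR FLASH)
sequence.  After an (assumed ideal) saturation pulse, magnetization recovers
for a delay ``TD``, then ``n`` phase-encoding steps of spoiled FLASH readout
(repetition time ``TR``, flip angle ``alpha``) are played out up to the
k-space center.  The signal of a pixel with longitudinal relaxation time
``T1`` is

    SI = c * [ (1 - e^(-TD/T1)) * a^(n-1)
               + (1 - e^(-TR/T1)) * (1 - a^(n-1)) / (1 - a) ],
    a  = cos(alpha) * e^(-TR/T1),

where ``c`` is a scaling factor proportional to the equilibrium
magnetization (coil gain x proton density), assumed constant over the
dynamic series.  Contrast agent shortens T1 according to the fast-exchange
relaxivity relation

    1/T1 = 1/T1_0 + r1 * [CA],

with native (pre-contrast) ``T1_0`` and relaxivity ``r1`` in
L·mmol^-1·s^-1.  Concentration quantification therefore proceeds per pixel
as: calibrate ``c`` from the pre-contrast baseline signal and the native T1,
invert the signal equation for T1 at every timepoint, and convert T1 to
concentration.

All times are seconds internally; the config reader converts protocol values
stated in milliseconds at the boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .errors import CalibrationError, ConfigurationError, DomainError

__all__ = [
    "ProtocolParams",
    "CalibratedPixel",
    "sr_flash_signal",
    "estimate_scaling_factor",
    "invert_signal_to_t1",
    "t1_to_concentration",
    "concentration_to_t1",
    "convert_curve_to_concentration",
    "convert_series_to_concentration",
    "DEFAULT_BRACKET",
]

#: Default T1 search bracket for signal inversion, seconds.
DEFAULT_BRACKET = (0.005, 5.0)

#: Absolute tolerance of the T1 root search, seconds.
T1_SOLVER_XTOL = 1e-6


@dataclass(frozen=True)
class ProtocolParams:
    """Acquisition parameters of the SR FLASH readout.

    Parameters
    ----------
    tr : float
        Repetition time per phase-encoding step, seconds.
    td : float
        Delay between the saturation pulse and the start of the FLASH
        readout, seconds.  This is distinct from the protocol TI (delay to
        the k-space *center*); the signal equation consumes TD and ``n_pe``.
    flip_angle : float
        Readout flip angle, radians.
    n_pe : int
        Number of phase-encoding steps from acquisition start to the
        k-space center.
    r1 : float
        Longitudinal relaxivity of the contrast agent, L·mmol^-1·s^-1.
    """

    tr: float = 2.2e-3
    td: float = 21.2e-3
    flip_angle: float = math.radians(12.0)
    n_pe: int = 31
    r1: float = 5.0

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise ConfigurationError(f"tr must be > 0, got {self.tr}")
        if self.td < 0:
            raise ConfigurationError(f"td must be >= 0, got {self.td}")
        if not 0 < self.flip_angle < math.pi / 2:
            raise ConfigurationError(
                f"flip_angle must be in (0, pi/2) rad, got {self.flip_angle}"
            )
        if int(self.n_pe) != self.n_pe or self.n_pe < 1:
            raise ConfigurationError(f"n_pe must be an integer >= 1, got {self.n_pe}")
        if not self.r1 > 0:
            raise ConfigurationError(f"r1 must be > 0, got {self.r1}")

    @classmethod
    def from_ms(
        cls,
        tr_ms: float = 2.2,
        td_ms: float = 21.2,
        flip_angle_deg: float = 12.0,
        n_pe: int = 31,
        r1: float = 5.0,
    ) -> "ProtocolParams":
        """Build from protocol-sheet units (milliseconds, degrees)."""
        return cls(
            tr=tr_ms * 1e-3,
            td=td_ms * 1e-3,
            flip_angle=math.radians(flip_angle_deg),
            n_pe=int(n_pe),
            r1=r1,
        )

    def replace(self, **kwargs) -> "ProtocolParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CalibratedPixel:
    """Per-pixel calibration of the signal model.

    ``c`` is chosen so the forward model at the native T1 reproduces the
    measured pre-contrast baseline signal exactly.
    """

    c: float
    t1_native: float
    baseline_si: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise CalibrationError(f"scaling factor must be > 0, got {self.c}")
        if not self.t1_native > 0:
            raise DomainError(f"t1_native must be > 0, got {self.t1_native}")

    @classmethod
    def from_baseline(
        cls, baseline_si: float, t1_native: float, params: "ProtocolParams"
    ) -> "CalibratedPixel":
        """Calibrate ``c`` so the forward model reproduces the baseline."""
        c = estimate_scaling_factor(baseline_si, t1_native, params)
        return cls(c=c, t1_native=t1_native, baseline_si=baseline_si)


def _unit_signal(t1, params: ProtocolParams):
    """Signal of the SR FLASH model at unit scaling factor (vectorized)."""
    t1 = np.asarray(t1, dtype=float)
    a = np.cos(params.flip_angle) * np.exp(-params.tr / t1)
    an1 = a ** (params.n_pe - 1)
    sat = (1.0 - np.exp(-params.td / t1)) * an1
    approach = (1.0 - np.exp(-params.tr / t1)) * (1.0 - an1) / (1.0 - a)
    return sat + approach


def sr_flash_signal(t1, c, params: ProtocolParams | None = None):
    """Forward SR FLASH signal for longitudinal relaxation time ``t1``.

    Strictly positive and strictly decreasing in ``t1`` over the
    physiological range for the default protocol.  Broadcasts over ``t1``.

    Parameters
    ----------
    t1 : float or array_like
        Longitudinal relaxation time, seconds; must be > 0.
    c : float
        Scaling factor (equilibrium-magnetization scale); must be > 0.
    params : ProtocolParams, optional
        Acquisition parameters; defaults to the reference protocol.
    """
    params = params or ProtocolParams()
    t1_arr = np.asarray(t1, dtype=float)
    if np.any(t1_arr <= 0):
        raise DomainError("t1 must be > 0")
    if not c > 0:
        raise DomainError(f"c must be > 0, got {c}")
    out = c * _unit_signal(t1_arr, params)
    return float(out) if np.isscalar(t1) or out.ndim == 0 else out


def estimate_scaling_factor(
    baseline_si: float, t1_native: float, params: ProtocolParams | None = None
) -> float:
    """Calibrate the scaling factor ``c`` from the pre-contrast baseline.

    Closed form: ``c = baseline_si / SI(t1_native; c=1)``, so the forward
    model at the native T1 reproduces the baseline exactly.

    Raises
    ------
    CalibrationError
        If ``baseline_si`` is not positive (corrupted baseline).
    """
    params = params or ProtocolParams()
    if not baseline_si > 0:
        raise CalibrationError(f"baseline signal must be > 0, got {baseline_si}")
    if not t1_native > 0:
        raise DomainError(f"t1_native must be > 0, got {t1_native}")
    return baseline_si / float(_unit_signal(t1_native, params))


def _check_monotone_bracket(c, params, bracket):
    lo, hi = bracket
    if not 0 < lo < hi:
        raise ConfigurationError(f"invalid bracket {bracket}")
    si_lo = c * float(_unit_signal(lo, params))
    si_hi = c * float(_unit_signal(hi, params))
    if not si_lo > si_hi:
        raise ConfigurationError(
            "signal model is not decreasing over the bracket; "
            "check protocol parameters"
        )
    return si_lo, si_hi


def invert_signal_to_t1(
    si,
    c: float,
    params: ProtocolParams | None = None,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    return_clamped: bool = False,
):
    """Invert the SR FLASH signal equation for T1 by bracketed root finding.

    The model is strictly monotone (decreasing) in T1 over the bracket,
    guaranteeing a unique root; a Brent-type solver with absolute tolerance
    ``1e-6`` s is used.  Signals outside the attainable range (noise pushing
    SI above the short-T1 asymptote or below the long-T1 floor) are clamped
    to the corresponding bracket edge and flagged, with a summary warning.

    Parameters
    ----------
    si : float or array_like
        Measured signal(s).
    c : float
        Calibrated scaling factor.
    bracket : (float, float)
        T1 search interval, seconds.
    return_clamped : bool
        If True, also return a boolean array marking clamped entries.

    Returns
    -------
    t1 : float or ndarray
    clamped : bool or ndarray, only if ``return_clamped``
    """
    params = params or ProtocolParams()
    if not c > 0:
        raise DomainError(f"c must be > 0, got {c}")
    si_lo, si_hi = _check_monotone_bracket(c, params, bracket)
    lo, hi = bracket

    si_arr = np.atleast_1d(np.asarray(si, dtype=float))
    t1 = np.empty_like(si_arr)
    clamped = np.zeros(si_arr.shape, dtype=bool)

    flat_si = si_arr.ravel()
    flat_t1 = t1.ravel()
    flat_cl = clamped.ravel()

    def f(t1_val, target):
        return c * float(_unit_signal(t1_val, params)) - target

    for i, target in enumerate(flat_si):
        if target >= si_lo:
            flat_t1[i] = lo
            flat_cl[i] = True
        elif target <= si_hi:
            flat_t1[i] = hi
            flat_cl[i] = True
        else:
            flat_t1[i] = brentq(f, lo, hi, args=(target,), xtol=T1_SOLVER_XTOL)

    n_clamped = int(flat_cl.sum())
    if n_clamped:
        warnings.warn(
            f"{n_clamped}/{flat_si.size} signal value(s) outside the attainable "
            f"range for bracket {bracket}; clamped to the bracket edge",
            RuntimeWarning,
            stacklevel=2,
        )

    if np.isscalar(si):
        return (float(t1[0]), bool(clamped[0])) if return_clamped else float(t1[0])
    return (t1, clamped) if return_clamped else t1


def t1_to_concentration(t1, t1_native: float, r1: float):
    """Convert relaxation time to contrast-agent concentration (mmol/L).

    ``[CA] = (1/T1 - 1/T1_0) / r1``; zero at the native state, strictly
    decreasing in ``t1``.  Negative values (noise driving T1 above native)
    are returned as-is; clipping is left to the caller.
    """
    t1_arr = np.asarray(t1, dtype=float)
    if np.any(t1_arr <= 0) or not t1_native > 0:
        raise DomainError("t1 and t1_native must be > 0")
    if not r1 > 0:
        raise DomainError(f"r1 must be > 0, got {r1}")
    out = (1.0 / t1_arr - 1.0 / t1_native) / r1
    return float(out) if np.isscalar(t1) or out.ndim == 0 else out


def concentration_to_t1(concentration, t1_native: float, r1: float):
    """Inverse of :func:`t1_to_concentration` (forward relaxivity relation)."""
    if not t1_native > 0 or not r1 > 0:
        raise DomainError("t1_native and r1 must be > 0")
    conc = np.asarray(concentration, dtype=float)
    rate = 1.0 / t1_native + r1 * conc
    if np.any(rate <= 0):
        raise DomainError("concentration drives 1/T1 non-positive")
    out = 1.0 / rate
    return float(out) if np.isscalar(concentration) or out.ndim == 0 else out


def convert_curve_to_concentration(
    values,
    baseline_si: float,
    t1_native: float,
    params: ProtocolParams | None = None,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    clip_negative: bool = False,
    return_clamped: bool = False,
):
    """Convert one signal-time course to concentration (mmol/L).

    Calibrates ``c`` from the baseline and native T1, inverts the signal
    model per timepoint, and applies the relaxivity relation.  Baseline
    timepoints map to approximately zero concentration.
    """
    params = params or ProtocolParams()
    c = estimate_scaling_factor(baseline_si, t1_native, params)
    t1, clamped = invert_signal_to_t1(
        np.asarray(values, dtype=float), c, params, bracket, return_clamped=True
    )
    conc = t1_to_concentration(t1, t1_native, params.r1)
    if clip_negative:
        conc = np.clip(conc, 0.0, None)
    return (conc, clamped) if return_clamped else conc


def convert_series_to_concentration(
    frames,
    baseline_map,
    t1_native_map,
    params: ProtocolParams | None = None,
    mask=None,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    clip_negative: bool = False,
):
    """Convert a dynamic image stack to a concentration stack, per pixel.

    Parameters
    ----------
    frames : ndarray, shape (T, R, C)
        Signal stack.
    baseline_map : ndarray, shape (R, C)
        Per-pixel pre-contrast baseline signal.
    t1_native_map : ndarray, shape (R, C)
        Per-pixel native T1, seconds.
    mask : ndarray of bool, shape (R, C), optional
        Pixels to convert; others are NaN in the output.

    Returns
    -------
    conc : ndarray, shape (T, R, C)
        Concentration in mmol/L, NaN outside the mask and at invalid pixels
        (non-positive baseline or native T1).
    flags : ndarray of bool, shape (T, R, C)
        True where the signal had to be clamped to the inversion bracket.
    """
    params = params or ProtocolParams()
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise DomainError("frames must be a (T, R, C) stack")
    n_t = frames.shape[0]
    shape = frames.shape[1:]
    baseline_map = np.asarray(baseline_map, dtype=float)
    t1_native_map = np.asarray(t1_native_map, dtype=float)
    if baseline_map.shape != shape or t1_native_map.shape != shape:
        raise DomainError("baseline_map and t1_native_map must match frame shape")
    if mask is None:
        mask = np.ones(shape, dtype=bool)

    conc = np.full((n_t,) + shape, np.nan)
    flags = np.zeros((n_t,) + shape, dtype=bool)

    rows, cols = np.nonzero(mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for r, col in zip(rows, cols):
            b = baseline_map[r, col]
            t1n = t1_native_map[r, col]
            if not (b > 0 and t1n > 0 and np.isfinite(b) and np.isfinite(t1n)):
                continue  # invalid pixel stays NaN-masked
            conc[:, r, col], flags[:, r, col] = convert_curve_to_concentration(
                frames[:, r, col],
                b,
                t1n,
                params,
                bracket,
                clip_negative,
                return_clamped=True,
            )
    return conc, flags
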