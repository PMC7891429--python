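"""Fermi-function constrained deconvolution for myocardial blood flow.

Tracer kinetics relate the tissue concentration curve to the arterial input
function (AIF) through a causal convolution with the tissue impulse
response h(t):

    C_tissue(t) = (C_aif * h)(t)

Constrained deconvolution models h with a Fermi function

    h(t) = A * (1 + b) / (1 + b * e^(t/k)),   b = e^(-tau/k),

equivalently A * (1 + e^(-tau/k)) / (1 + e^((t - tau)/k)): a plateau of
width ~tau followed by a decay of steepness k, normalized so h(0) = A
exactly.  By the central-volume theorem the impulse-response value at
t = 0 estimates flow: MBF = A * 60 / rho with myocardial tissue density
rho = 1.05 g/mL (A in s^-1 per mL of tissue, MBF in mL/(min·g)).

The AIF-to-tissue transit delay is handled by fitting at each candidate
time shift on a grid and keeping the shift with the minimal residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .curves import ConcentrationCurve
from .errors import InputError

__all__ = [
    "TISSUE_DENSITY_G_PER_ML",
    "FermiParams",
    "FermiFitResult",
    "fermi_impulse",
    "convolve_response",
    "fit_fermi",
    "compute_mbf_map",
    "aggregate_mbf",
    "amplitude_to_mbf",
    "mbf_to_amplitude",
    "DEFAULT_SHIFT_FRAMES",
]

#: Accepted myocardial tissue density, g/mL.
TISSUE_DENSITY_G_PER_ML = 1.05

#: Default time-shift search grid, in frames (multiplied by dt at fit time).
DEFAULT_SHIFT_FRAMES = (-2, -1, 0, 1, 2, 3)

# Fit bounds: A in s^-1, tau and k in s.  Fermi fits are mildly non-convex;
# bounds plus a few jittered restarts keep the solver out of flat corners.
_BOUNDS_LO = np.array([0.0, 0.0, 0.1])
_BOUNDS_HI = np.array([10.0, 30.0, 60.0])
_N_MULTISTART = 3


@dataclass(frozen=True)
class FermiParams:
    """Fermi impulse-response parameters.

    amplitude : s^-1, impulse-response value at t = 0 (the flow parameter)
    tau : s, shoulder (plateau) width
    k_decay : s, decay steepness
    time_shift : s, AIF-to-tissue delay applied to the AIF
    """

    amplitude: float
    tau: float
    k_decay: float
    time_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InputError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.tau < 0:
            raise InputError(f"tau must be >= 0, got {self.tau}")
        if not self.k_decay > 0:
            raise InputError(f"k_decay must be > 0, got {self.k_decay}")


@dataclass(frozen=True)
class FermiFitResult:
    """Outcome of a single-pixel Fermi deconvolution."""

    params: FermiParams
    mbf: float
    rmse: float
    n_fit_points: int
    converged: bool


def amplitude_to_mbf(amplitude: float, density: float = TISSUE_DENSITY_G_PER_ML) -> float:
    """Convert the flow amplitude (s^-1) to MBF in mL/(min·g)."""
    return amplitude * 60.0 / density


def mbf_to_amplitude(mbf: float, density: float = TISSUE_DENSITY_G_PER_ML) -> float:
    """Convert MBF in mL/(min·g) to the impulse-response amplitude (s^-1)."""
    return mbf * density / 60.0


def fermi_impulse(t, params: FermiParams):
    """Evaluate the Fermi impulse response at times ``t >= 0`` (s^-1).

    ``h(0) = amplitude`` exactly; non-increasing in t; decays to zero.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("fermi_impulse requires t >= 0")
    b = np.exp(-params.tau / params.k_decay)
    e = np.exp(np.minimum(t / params.k_decay, 600.0))  # cap: h is 0 there anyway
    out = params.amplitude * (1.0 + b) / (1.0 + b * e)
    return float(out) if out.ndim == 0 else out


def _shifted_aif(aif_values: np.ndarray, dt: float, shift: float) -> np.ndarray:
    """Sample the AIF at t - shift on its own uniform grid (linear interp)."""
    if shift == 0.0:
        return aif_values
    n = len(aif_values)
    grid = np.arange(n) * dt
    return np.interp(grid - shift, grid, aif_values, left=aif_values[0], right=aif_values[-1])


def convolve_response(
    aif: ConcentrationCurve | np.ndarray, params: FermiParams, dt: float
) -> np.ndarray:
    """Model tissue curve: causal discrete convolution of AIF and Fermi IR.

    Left-rectangle rule scaled by ``dt``; the AIF must already be on a
    uniform grid of spacing ``dt``.  Output has the AIF's length.
    """
    if isinstance(aif, ConcentrationCurve):
        diffs = np.diff(aif.times)
        if not np.allclose(diffs, dt, rtol=1e-6, atol=1e-12):
            raise InputError("AIF must be uniformly sampled at dt; resample first")
        values = aif.values
    else:
        values = np.asarray(aif, dtype=float)
    n = len(values)
    shifted = _shifted_aif(values, dt, params.time_shift)
    h = fermi_impulse(np.arange(n) * dt, params)
    return np.convolve(shifted, h)[:n] * dt


def _fit_single_shift(aif_values, tissue, dt, shift, x0, rng):
    """Bounded least squares of (A, tau, k) at one fixed time shift."""
    shifted = _shifted_aif(aif_values, dt, shift)
    n = len(tissue)
    t_grid = np.arange(n) * dt

    def residuals(x):
        amp, tau, k = x
        b = np.exp(-tau / k)
        h = amp * (1.0 + b) / (1.0 + b * np.exp(t_grid / k))
        return np.convolve(shifted, h)[:n] * dt - tissue

    def jacobian(x):
        # analytic dh/d(A, tau, k) convolved with the shifted AIF
        amp, tau, k = x
        b = np.exp(-tau / k)
        e = np.exp(t_grid / k)
        denom = 1.0 + b * e
        dh_da = (1.0 + b) / denom
        dh_db = amp * (1.0 - e) / denom**2
        dh_dtau = dh_db * (-b / k)
        dh_dk = (amp / (denom**2 * k**2)) * ((1.0 - e) * b * tau + (1.0 + b) * b * t_grid * e)
        cols = [np.convolve(shifted, d)[:n] * dt for d in (dh_da, dh_dtau, dh_dk)]
        return np.column_stack(cols)

    best = None
    start = np.clip(x0, _BOUNDS_LO + 1e-9, _BOUNDS_HI - 1e-9)
    for attempt in range(1 + _N_MULTISTART):
        try:
            res = least_squares(
                residuals,
                start,
                jac=jacobian,
                bounds=(_BOUNDS_LO, _BOUNDS_HI),
                method="trf",
                xtol=1e-9,
                ftol=1e-9,
                gtol=1e-9,
                max_nfev=100,
            )
        except Exception:
            res = None
        if res is not None and res.success and np.isfinite(res.cost):
            if best is None or res.cost < best.cost:
                best = res
            break  # converged; jittered restarts only on failure
        # jittered restart within bounds
        jitter = rng.uniform(0.5, 1.5, size=3)
        start = np.clip(x0 * jitter, _BOUNDS_LO + 1e-9, _BOUNDS_HI - 1e-9)
    return best


def fit_fermi(
    aif: ConcentrationCurve | np.ndarray,
    tissue: ConcentrationCurve | np.ndarray,
    shift_grid=None,
    dt: float | None = None,
    seed: int = 0,
) -> FermiFitResult:
    """Fermi-constrained deconvolution of one tissue curve against the AIF.

    Both curves must be truncated to the first pass and sampled on the same
    uniform grid.  For every candidate time shift the three Fermi
    parameters are fitted by bounded least squares (warm-started from the
    previous shift's solution); the fit with the minimal residual norm over
    the shift grid is returned, with MBF derived from the amplitude.

    Parameters
    ----------
    shift_grid : sequence of float, optional
        Candidate AIF-to-tissue delays in seconds; defaults to
        ``DEFAULT_SHIFT_FRAMES`` frames at the curve resolution.
    seed : int
        Seed for the jittered multi-start fallback.
    """
    if isinstance(aif, ConcentrationCurve):
        diffs = np.diff(aif.times)
        if dt is None:
            dt = float(np.median(diffs))
        if not np.allclose(diffs, dt, rtol=1e-6, atol=1e-12):
            raise InputError("AIF must be uniformly sampled; resample first")
        aif_values = aif.values
    else:
        aif_values = np.asarray(aif, dtype=float)
        if dt is None:
            raise InputError("dt required when the AIF is a bare array")
    tissue_values = tissue.values if isinstance(tissue, ConcentrationCurve) else np.asarray(tissue, float)
    if len(tissue_values) != len(aif_values):
        raise InputError("AIF and tissue curves must have equal length")
    n = len(tissue_values)
    if n < 8:
        raise InputError(f"need >= 8 fit points, got {n}")
    if shift_grid is None:
        shift_grid = [f * dt for f in DEFAULT_SHIFT_FRAMES]

    rng = np.random.default_rng(seed)

    # peak / peak-integral heuristic for the flow amplitude start value
    cum = np.cumsum(aif_values) * dt
    denom = cum[int(np.argmax(aif_values))]
    if denom <= 0:
        denom = max(cum[-1], dt)
    a0 = float(np.clip(np.max(tissue_values) / max(denom, 1e-12), 1e-4, 5.0))
    x0 = np.array([a0, 2.0, 5.0])

    best = None
    best_shift = 0.0
    warm = x0
    for shift in shift_grid:
        res = _fit_single_shift(aif_values, tissue_values, dt, shift, warm, rng)
        if res is None:
            continue
        warm = res.x  # warm start the next shift
        if best is None or res.cost < best.cost:
            best = res
            best_shift = float(shift)

    if best is None:
        params = FermiParams(0.0, 0.0, 1.0, 0.0)
        return FermiFitResult(params, float("nan"), float("nan"), n, False)

    amp, tau, k = best.x
    params = FermiParams(float(amp), float(tau), float(k), best_shift)
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    return FermiFitResult(params, amplitude_to_mbf(float(amp)), rmse, n, True)


def _batch_model(x: np.ndarray, t_grid: np.ndarray, conv_op: np.ndarray) -> np.ndarray:
    """Modeled tissue curves for a batch of Fermi parameter triples.

    ``x`` is (p, 3) = (amplitude, tau, k); ``conv_op`` the (n, n) causal
    convolution operator of the (shifted) AIF scaled by dt.
    """
    amp, tau, k = x[:, 0:1], x[:, 1:2], x[:, 2:3]
    b = np.exp(-tau / k)
    e = np.exp(np.minimum(t_grid[None, :] / k, 600.0))
    h = amp * (1.0 + b) / (1.0 + b * e)
    return h @ conv_op.T


def _batch_model_jac(x, t_grid, conv_op):
    """Model plus analytic Jacobian (p, n, 3) for the batched LM solver."""
    amp, tau, k = x[:, 0:1], x[:, 1:2], x[:, 2:3]
    b = np.exp(-tau / k)
    e = np.exp(np.minimum(t_grid[None, :] / k, 600.0))
    denom = 1.0 + b * e
    h = amp * (1.0 + b) / denom
    dh_da = (1.0 + b) / denom
    dh_db = amp * (1.0 - e) / denom**2
    dh_dtau = dh_db * (-b / k)
    dh_dk = (amp / (denom**2 * k**2)) * ((1.0 - e) * b * tau + (1.0 + b) * b * t_grid[None, :] * e)
    model = h @ conv_op.T
    jac = np.stack([dh_da @ conv_op.T, dh_dtau @ conv_op.T, dh_dk @ conv_op.T], axis=2)
    return model, jac


def _batch_lm(tissue, t_grid, conv_op, x0, max_iter=80, ftol=1e-12):
    """Projected Levenberg-Marquardt over a batch of pixels (3 parameters).

    Same objective, bounds and model as the scalar path; all pixels iterate
    simultaneously with per-pixel damping.  Returns (x, cost).
    """
    x = np.clip(x0, _BOUNDS_LO, _BOUNDS_HI)
    lam = np.full(len(x), 1e-3)
    model, jac = _batch_model_jac(x, t_grid, conv_op)
    resid = model - tissue
    cost = np.einsum("pn,pn->p", resid, resid)
    stalled = 0
    for _ in range(max_iter):
        hess = np.einsum("pnc,pnd->pcd", jac, jac)
        grad = np.einsum("pnc,pn->pc", jac, resid)
        diag = np.einsum("pcc->pc", hess)
        damped = hess + lam[:, None, None] * (diag[:, :, None] * np.eye(3) + 1e-12 * np.eye(3))
        try:
            step = -np.linalg.solve(damped, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = -np.linalg.solve(damped + 1e-8 * np.eye(3), grad[:, :, None])[:, :, 0]
        x_new = np.clip(x + step, _BOUNDS_LO, _BOUNDS_HI)
        trial = _batch_model(x_new, t_grid, conv_op)
        resid_new = trial - tissue
        cost_new = np.einsum("pn,pn->p", resid_new, resid_new)
        improved = cost_new < cost
        x[improved] = x_new[improved]
        cost_rel_drop = np.where(cost > 0, (cost - cost_new) / np.maximum(cost, 1e-300), 0.0)
        cost[improved] = cost_new[improved]
        lam = np.clip(np.where(improved, lam * 0.3, lam * 3.0), 1e-12, 1e12)
        if not improved.any() or np.max(np.where(improved, cost_rel_drop, 0.0)) < ftol:
            stalled += 1
            if stalled >= 3:
                break
        else:
            stalled = 0
        model, jac = _batch_model_jac(x, t_grid, conv_op)
        resid = model - tissue
    return x, cost


def compute_mbf_map(
    conc_stack: np.ndarray,
    aif: ConcentrationCurve | np.ndarray,
    myo_mask: np.ndarray,
    shift_grid=None,
    dt: float | None = None,
    seed: int = 0,
    return_diagnostics: bool = False,
):
    """Pixelwise MBF by Fermi deconvolution over a myocardial mask.

    ``conc_stack`` (T, R, C) must already be converted to concentration and
    truncated to the first pass, on the same uniform grid as the AIF.
    Every masked pixel is deconvolved with the same objective, bounds and
    shift grid as :func:`fit_fermi`; pixels are batched through a
    vectorized Levenberg-Marquardt solver for speed.  Non-converged pixels
    are NaN in the map.

    Returns
    -------
    mbf_map : ndarray (R, C), NaN outside the mask / where not converged
    diagnostics : dict of ndarrays (rmse, shift, converged), optional
    """
    myo_mask = np.asarray(myo_mask, dtype=bool)
    conc_stack = np.asarray(conc_stack, dtype=float)
    if conc_stack.ndim != 3 or conc_stack.shape[1:] != myo_mask.shape:
        raise InputError("conc_stack must be (T, R, C) matching the mask")
    if not myo_mask.any():
        raise InputError("myocardial mask is empty")

    if isinstance(aif, ConcentrationCurve):
        diffs = np.diff(aif.times)
        if dt is None:
            dt = float(np.median(diffs))
        if not np.allclose(diffs, dt, rtol=1e-6, atol=1e-12):
            raise InputError("AIF must be uniformly sampled; resample first")
        aif_values = aif.values
    else:
        aif_values = np.asarray(aif, dtype=float)
        if dt is None:
            raise InputError("dt required when the AIF is a bare array")
    n = conc_stack.shape[0]
    if len(aif_values) != n:
        raise InputError("AIF length must match the concentration stack")
    if n < 8:
        raise InputError(f"need >= 8 fit points, got {n}")
    if shift_grid is None:
        shift_grid = [f * dt for f in DEFAULT_SHIFT_FRAMES]
    t_grid = np.arange(n) * dt

    shape = myo_mask.shape
    tissue_all = conc_stack[:, myo_mask].T  # (p, n)
    finite = np.all(np.isfinite(tissue_all), axis=1)
    tissue = tissue_all[finite]
    p = len(tissue)

    mbf_map = np.full(shape, np.nan)
    rmse_map = np.full(shape, np.nan)
    shift_map = np.full(shape, np.nan)
    conv_map = np.zeros(shape, dtype=bool)
    if p == 0:
        if return_diagnostics:
            return mbf_map, {"rmse": rmse_map, "shift": shift_map, "converged": conv_map}
        return mbf_map

    # peak / peak-integral heuristic start values per pixel
    cum = np.cumsum(aif_values) * dt
    denom = max(cum[int(np.argmax(aif_values))], 1e-12)
    a0 = np.clip(tissue.max(axis=1) / denom, 1e-4, 5.0)
    x0 = np.column_stack([a0, np.full(p, 2.0), np.full(p, 5.0)])

    best_x = None
    best_cost = np.full(p, np.inf)
    best_shift = np.zeros(p)
    warm = x0
    rng = np.random.default_rng(seed)
    for shift in shift_grid:
        shifted = _shifted_aif(aif_values, dt, float(shift))
        conv_op = np.tril(
            np.array([[shifted[i - j] if i >= j else 0.0 for j in range(n)] for i in range(n)])
        ) * dt
        # dual start: previous shift's solution and the fresh heuristic;
        # the Fermi objective is mildly non-convex and either start alone
        # can stall in a shift-dependent local minimum
        x, cost = _batch_lm(tissue, t_grid, conv_op, warm.copy())
        x_h, cost_h = _batch_lm(tissue, t_grid, conv_op, x0.copy())
        take = cost_h < cost
        x[take], cost[take] = x_h[take], cost_h[take]
        bad = ~np.isfinite(cost)
        for _ in range(_N_MULTISTART):
            if not bad.any():
                break
            jitter = rng.uniform(0.5, 1.5, size=(int(bad.sum()), 3))
            x_r, cost_r = _batch_lm(tissue[bad], t_grid, conv_op, x0[bad] * jitter)
            x[bad], cost[bad] = x_r, cost_r
            bad = ~np.isfinite(cost)
        warm = x
        better = cost < best_cost
        if best_x is None:
            best_x = x.copy()
            best_cost = cost.copy()
            best_shift[:] = shift
        else:
            best_x[better] = x[better]
            best_cost[better] = cost[better]
            best_shift[better] = shift

    converged = np.isfinite(best_cost)
    rows, cols = np.nonzero(myo_mask)
    rows, cols = rows[finite], cols[finite]
    mbf_map[rows[converged], cols[converged]] = amplitude_to_mbf(1.0) * best_x[converged, 0]
    rmse_map[rows[converged], cols[converged]] = np.sqrt(best_cost[converged] / n)
    shift_map[rows[converged], cols[converged]] = best_shift[converged]
    conv_map[rows[converged], cols[converged]] = True

    if return_diagnostics:
        return mbf_map, {"rmse": rmse_map, "shift": shift_map, "converged": conv_map}
    return mbf_map


def aggregate_mbf(mbf_map: np.ndarray, region_masks: dict) -> dict:
    """Per-region mean MBF over converged (finite) pixels.

    Returns ``{region: {"mean": float, "n_pixels": int, "n_excluded": int}}``;
    a region with zero converged pixels yields NaN with a warning.
    """
    mbf_map = np.asarray(mbf_map, dtype=float)
    out = {}
    for name, mask in region_masks.items():
        mask = np.asarray(mask, dtype=bool)
        vals = mbf_map[mask]
        good = np.isfinite(vals)
        n_good = int(good.sum())
        if n_good == 0:
            warnings.warn(f"region {name!r} has no converged pixels", RuntimeWarning)
            mean = float("nan")
        else:
            mean = float(vals[good].mean())
        out[name] = {"mean": mean, "n_pixels": n_good, "n_excluded": int(mask.sum()) - n_good}
    return out
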