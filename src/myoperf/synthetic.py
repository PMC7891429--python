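"""Synthetic DCE phantom with known ground-truth MBF.

Emulates a mid-ventricular short-axis slice: a circular LV blood pool
carrying a gamma-variate first-pass concentration curve (with a delayed
recirculation bump), an annular myocardium whose tissue curves are the
convolution of the arterial input with a Fermi impulse response at known
MBF, and signal formation through the saturation-recovery FLASH forward
model with per-tissue native T1 and scaling factors, plus Gaussian or
Rician noise at a configured baseline SNR.

The native T1 map has regional heterogeneity: a smooth raised-cosine
elevation centered on the "deficit" sector (scaled so the deficit-sector
*mean* hits the configured value) plus a small angular ripple, so that
successively finer sector averages keep resolving real structure.  Default
central values are typical of a chronic coronary-heart-disease cohort at
3T: diastolic blood T1 1891 ms, myocardial 1259 ms, deficit-segment mean
1425 ms, resting background MBF 0.61 mL/(min·g).

The generator uses only the *forward* signal model; the pipeline's
inversion path is never called here, so generative round trips are genuine
cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .curves import ConcentrationCurve, DCESeries
from .errors import ConfigurationError
from .fermi import FermiParams, convolve_response, mbf_to_amplitude
from .regions import MyocardialGeometry, build_annulus_mask, sectorize
from .signal_model import ProtocolParams, concentration_to_t1, sr_flash_signal

__all__ = [
    "AIFParams",
    "PhantomConfig",
    "Phantom",
    "gamma_variate_aif",
    "generate_phantom",
    "default_cohort_config",
]

_DEFICIT_BUMP_MEAN = 0.5 + 1.0 / np.pi  # sector-mean of the raised cosine


@dataclass(frozen=True)
class AIFParams:
    """Gamma-variate first-pass arterial input with recirculation.

    ``A * (t - t0)^alpha * exp(-(t - t0)/beta)`` for ``t > t0`` (else 0),
    with the overall scale calibrated so the first-pass peak equals
    ``peak`` mmol/L; the recirculation bump is a scaled, delayed copy.
    """

    t0: float = 8.0
    shape_alpha: float = 3.0
    rate_beta: float = 2.0
    peak: float = 3.72
    recirc_fraction: float = 0.18
    recirc_delay: float = 13.0

    @property
    def scale(self) -> float:
        """Amplitude giving the requested first-pass peak (analytic)."""
        tp = self.shape_alpha * self.rate_beta  # mode of the gamma variate
        return self.peak / (tp**self.shape_alpha * np.exp(-self.shape_alpha))


def gamma_variate_aif(times, aif_params: AIFParams) -> ConcentrationCurve:
    """Evaluate the noiseless AIF concentration (mmol/L) at ``times``."""
    times = np.asarray(times, dtype=float)

    def first_pass(t):
        dt = t - aif_params.t0
        out = np.zeros_like(t)
        pos = dt > 0
        out[pos] = (
            aif_params.scale
            * dt[pos] ** aif_params.shape_alpha
            * np.exp(-dt[pos] / aif_params.rate_beta)
        )
        return out

    values = first_pass(times)
    if aif_params.recirc_fraction > 0:
        values = values + aif_params.recirc_fraction * first_pass(
            times - aif_params.recirc_delay
        )
    return ConcentrationCurve(times, values, units="mmol/L")


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of the synthetic slice (defaults = cohort values)."""

    image_shape: tuple[int, int] = (64, 64)
    endo_radius: float = 9.0  # diastole, px
    systole_endo_radius: float = 7.5  # wall thickens in systole
    epi_radius: float = 15.0
    blood_roi_radius: float = 5.0
    n_frames: int = 70  # one frame per heartbeat
    rr_interval: float = 1.0  # s
    aif: AIFParams = field(default_factory=AIFParams)
    # ground-truth perfusion (6 sectors, mid-ventricular AHA layout)
    n_sectors: int = 6
    true_mbf_background: float = 0.61  # mL/(min·g)
    true_mbf_deficit: float = 0.35
    deficit_sectors: tuple[int, ...] = (4,)  # 1-based, 4 = inferior
    fermi_tau: float = 2.5  # s
    fermi_k: float = 4.0  # s
    # native T1 (s) per cardiac phase
    t1_blood_diastole: float = 1.891
    t1_blood_systole: float = 1.897
    t1_myo_diastole: float = 1.259
    t1_myo_systole: float = 1.249
    t1_deficit_diastole: float = 1.425
    t1_deficit_systole: float = 1.415
    t1_ripple_amp: float = 0.015  # s, sub-sector angular structure
    t1_ripple_freq: int = 2
    t1_ripple_phase: float = 1.0
    # signal formation
    c_blood: float = 1000.0  # proton-density-like scaling factors
    c_myo: float = 1000.0
    background_t1: float = 1.0
    c_background: float = 500.0
    snr: float = 20.0  # baseline-signal SNR; np.inf disables noise
    noise_model: str = "gaussian"  # or "rician"
    reference_angle: float = np.pi / 2
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.epi_radius <= self.endo_radius or self.epi_radius <= self.systole_endo_radius:
            raise ConfigurationError("epi radius must exceed endo radius")
        if self.blood_roi_radius >= min(self.endo_radius, self.systole_endo_radius):
            raise ConfigurationError("blood ROI must fit inside the endo contour")
        if min(self.image_shape) < 2 * self.epi_radius + 4:
            raise ConfigurationError("image too small for the epicardial contour")
        if not self.snr > 0:
            raise ConfigurationError("snr must be > 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        if not all(1 <= s <= self.n_sectors for s in self.deficit_sectors):
            raise ConfigurationError("deficit sector index out of range")
        if self.true_mbf_background < 0 or self.true_mbf_deficit < 0:
            raise ConfigurationError("true MBF must be >= 0")
        # the generator enforces the observed deficit phenotype:
        # elevated native T1 together with reduced flow
        if self.deficit_sectors:
            if not (
                self.t1_deficit_diastole > self.t1_myo_diastole
                and self.t1_deficit_systole > self.t1_myo_systole
            ):
                raise ConfigurationError("deficit T1 must exceed background T1")
            if not self.true_mbf_deficit < self.true_mbf_background:
                raise ConfigurationError("deficit MBF must be below background MBF")

    def replace(self, **kwargs) -> "PhantomConfig":
        return replace(self, **kwargs)

    def true_mbf_sectors(self) -> np.ndarray:
        mbf = np.full(self.n_sectors, self.true_mbf_background)
        for s in self.deficit_sectors:
            mbf[s - 1] = self.true_mbf_deficit
        return mbf

    def t1_values(self, phase: str) -> dict[str, float]:
        if phase == "diastole":
            return {
                "blood": self.t1_blood_diastole,
                "myocardium": self.t1_myo_diastole,
                "deficit": self.t1_deficit_diastole,
            }
        if phase == "systole":
            return {
                "blood": self.t1_blood_systole,
                "myocardium": self.t1_myo_systole,
                "deficit": self.t1_deficit_systole,
            }
        raise ConfigurationError(f"unknown phase {phase!r}")


def default_cohort_config() -> PhantomConfig:
    """Phantom whose T1 and MBF central values equal the cohort means."""
    return PhantomConfig()


@dataclass
class Phantom:
    """A generated phantom: inputs for the pipeline plus ground truth."""

    series: DCESeries
    t1_map: np.ndarray
    geometry: MyocardialGeometry
    blood_roi: np.ndarray
    myo_mask: np.ndarray
    sector_labels: np.ndarray
    truth: dict[str, Any]
    config: PhantomConfig
    phase: str


def _circle(center, radius, n_vertices=128) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)])


def _myo_t1_profile(config: PhantomConfig, phase: str, rel_theta: np.ndarray) -> np.ndarray:
    """Smooth per-pixel native myocardial T1 as a function of sector angle."""
    t1 = config.t1_values(phase)
    base = t1["myocardium"]
    width = 2.0 * np.pi / config.n_sectors
    amp = (t1["deficit"] - base) / _DEFICIT_BUMP_MEAN
    out = np.full_like(rel_theta, base)
    for s in config.deficit_sectors:
        center = (s - 0.5) * width
        d = np.angle(np.exp(1j * (rel_theta - center)))  # wrapped distance
        inside = np.abs(d) < width
        out[inside] += amp * 0.5 * (1.0 + np.cos(np.pi * d[inside] / width))
    out += config.t1_ripple_amp * np.sin(
        config.t1_ripple_freq * rel_theta + config.t1_ripple_phase
    )
    return out


def generate_phantom(
    config: PhantomConfig,
    phase: str = "diastole",
    params: ProtocolParams | None = None,
) -> Phantom:
    """Generate one cardiac-phase phantom with its ground-truth bundle.

    Fixed ``config.seed`` gives a bit-identical phantom on repeated calls
    (the noise stream is keyed by seed and phase).
    """
    params = params or ProtocolParams()
    t1 = config.t1_values(phase)
    shape = config.image_shape
    center = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)  # (x, y)
    endo_r = config.endo_radius if phase == "diastole" else config.systole_endo_radius

    geometry = MyocardialGeometry(
        endo_contour=_circle(center, endo_r),
        epi_contour=_circle(center, config.epi_radius),
        centroid=center,
        reference_angle=config.reference_angle,
    )
    myo_mask = build_annulus_mask(geometry, shape)
    labels = sectorize(geometry, config.n_sectors, shape)

    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    radius = np.hypot(cols - center[0], rows - center[1])
    blood_mask = radius < endo_r - 0.5  # interior blood, margin off the wall
    blood_roi = radius <= config.blood_roi_radius

    # ---- ground-truth concentration curves -------------------------------
    times = np.arange(config.n_frames) * config.rr_interval
    dt = config.rr_interval
    aif = gamma_variate_aif(times, config.aif)

    mbf_sectors = config.true_mbf_sectors()
    tissue_conc = np.zeros((config.n_sectors, config.n_frames))
    for s in range(config.n_sectors):
        fp = FermiParams(
            amplitude=mbf_to_amplitude(mbf_sectors[s]),
            tau=config.fermi_tau,
            k_decay=config.fermi_k,
        )
        tissue_conc[s] = convolve_response(aif.values, fp, dt)

    arrival_index = int(np.argmax(aif.values > 0))
    peak = int(np.argmax(aif.values))
    valley_index = config.n_frames - 1
    for i in range(peak + 1, config.n_frames - 1):
        if aif.values[i + 1] > aif.values[i]:
            valley_index = i
            break
    aif.arrival_index = arrival_index
    aif.first_pass_end_index = valley_index

    # ---- native T1 map ----------------------------------------------------
    rel_theta = np.mod(
        np.arctan2(center[1] - rows, cols - center[0]) - config.reference_angle,
        2.0 * np.pi,
    )
    t1_map = np.full(shape, np.nan)
    t1_map[blood_mask] = t1["blood"]
    myo_t1_px = _myo_t1_profile(config, phase, rel_theta)
    t1_map[myo_mask] = myo_t1_px[myo_mask]

    # ---- forward signal formation -----------------------------------------
    frames = np.empty((config.n_frames,) + shape)
    frames[:] = config.c_background * float(
        sr_flash_signal(config.background_t1, 1.0, params)
    )

    t1_blood_t = concentration_to_t1(aif.values, t1["blood"], params.r1)
    blood_si = sr_flash_signal(t1_blood_t, config.c_blood, params)
    frames[:, blood_mask] = blood_si[:, None]

    true_mbf_map = np.full(shape, np.nan)
    for s in range(config.n_sectors):
        sel = myo_mask & (labels == s + 1)
        t1n = t1_map[sel]  # (npx,)
        rate = 1.0 / t1n[None, :] + params.r1 * tissue_conc[s][:, None]
        frames[:, sel] = config.c_myo * _forward_signal(1.0 / rate, params)
        true_mbf_map[sel] = mbf_sectors[s]

    # ---- noise ------------------------------------------------------------
    myo_baseline_si = float(np.mean(frames[0][myo_mask]))
    if np.isinf(config.snr):
        sigma = 0.0
    else:
        sigma = myo_baseline_si / config.snr
        rng = np.random.default_rng([config.seed, 0 if phase == "diastole" else 1])
        if config.noise_model == "gaussian":
            frames = frames + rng.normal(0.0, sigma, frames.shape)
        else:
            n1 = rng.normal(0.0, sigma, frames.shape)
            n2 = rng.normal(0.0, sigma, frames.shape)
            frames = np.hypot(frames + n1, n2)

    series = DCESeries(frames, times, cardiac_phase=phase)
    truth = {
        "mbf_map": true_mbf_map,
        "mbf_sectors": mbf_sectors,
        "aif": aif,
        "tissue_conc": tissue_conc,
        "arrival_index": arrival_index,
        "valley_index": valley_index,
        "noise_sigma": sigma,
        "myo_baseline_si": myo_baseline_si,
        "fermi": {"tau": config.fermi_tau, "k_decay": config.fermi_k},
        "t1": t1,
    }
    return Phantom(
        series, t1_map, geometry, blood_roi, myo_mask, labels, truth, config, phase
    )


def _forward_signal(t1_array: np.ndarray, params: ProtocolParams) -> np.ndarray:
    """Unit-scale SR FLASH forward model, vectorized (generator-side)."""
    a = np.cos(params.flip_angle) * np.exp(-params.tr / t1_array)
    an1 = a ** (params.n_pe - 1)
    return (1.0 - np.exp(-params.td / t1_array)) * an1 + (
        1.0 - np.exp(-params.tr / t1_array)
    ) * (1.0 - an1) / (1.0 - a)
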