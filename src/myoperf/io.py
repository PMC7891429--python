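"""File I/O: NIfTI stacks, masks, sidecar timing, configs, result tables.

Image stacks are stored as one 3D NIfTI volume with time as the third
axis and the frame times in a JSON sidecar; masks and maps as 2D NIfTI
(missing = NaN for float maps).  Protocol parameters come from a flat
key = value config (times in milliseconds, angle in degrees, matching how
protocols are printed on scanner sheets); phantom ground truth is JSON,
regional tables CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .curves import DCESeries
from .errors import InputError
from .regions import AHA_MID_SEGMENT_NAMES
from .signal_model import ProtocolParams

__all__ = [
    "save_series",
    "load_series",
    "save_map",
    "load_map",
    "save_mask",
    "load_mask",
    "read_protocol_config",
    "write_sector_table",
    "save_contours",
    "load_contours",
]


def _affine(pixel_spacing=(1.0, 1.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1] = pixel_spacing
    return aff


def save_series(series: DCESeries, path: str | Path) -> None:
    """Write a DCE series as NIfTI (row, col, time) plus a JSON sidecar."""
    path = Path(path)
    data = np.moveaxis(series.frames, 0, -1)
    nib.save(nib.Nifti1Image(data.astype(np.float32), _affine(series.pixel_spacing)), str(path))
    sidecar = {
        "frame_times_s": series.frame_times.tolist(),
        "cardiac_phase": series.cardiac_phase,
        "pixel_spacing_mm": list(series.pixel_spacing),
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_series(path: str | Path) -> DCESeries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    if not sidecar_path.exists():
        raise InputError(f"missing timing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    return DCESeries(
        data,
        np.asarray(sidecar["frame_times_s"], dtype=float),
        sidecar.get("cardiac_phase", "diastole"),
        tuple(sidecar.get("pixel_spacing_mm", (1.0, 1.0))),
    )


def save_map(array: np.ndarray, path: str | Path, pixel_spacing=(1.0, 1.0)) -> None:
    """Write a 2D float map (e.g. MBF or T1) as NIfTI; missing = NaN."""
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), _affine(pixel_spacing)), str(path))


def load_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine()), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def read_protocol_config(path: str | Path) -> ProtocolParams:
    """Read acquisition parameters from a flat YAML/key-value config.

    Recognized keys (protocol-sheet units): ``tr_ms``, ``td_ms``,
    ``flip_angle_deg``, ``n_pe``, ``r1``.  Missing keys fall back to the
    reference protocol defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"tr_ms", "td_ms", "flip_angle_deg", "n_pe", "r1"}
    unknown = set(raw) - known
    if unknown:
        raise InputError(f"unknown protocol keys: {sorted(unknown)}")
    return ProtocolParams.from_ms(**raw)


def write_sector_table(means: dict | np.ndarray, path: str | Path, quantity: str = "mbf") -> pd.DataFrame:
    """Write per-sector means as CSV, with AHA names for six sectors."""
    if isinstance(means, dict):
        sectors = sorted(means)
        values = [means[s]["mean"] if isinstance(means[s], dict) else means[s] for s in sectors]
        counts = [means[s].get("n_pixels") if isinstance(means[s], dict) else None for s in sectors]
    else:
        values = list(np.asarray(means, dtype=float))
        sectors = list(range(1, len(values) + 1))
        counts = [None] * len(values)
    df = pd.DataFrame({"sector": sectors, quantity: values, "n_pixels": counts})
    if len(df) == 6:
        df.insert(1, "aha_segment", list(AHA_MID_SEGMENT_NAMES))
    df.to_csv(path, index=False)
    return df


def save_contours(geometry, path: str | Path) -> None:
    """Write endo/epi contours and the reference angle as JSON."""
    payload = {
        "endo_contour_xy": np.asarray(geometry.endo_contour).tolist(),
        "epi_contour_xy": np.asarray(geometry.epi_contour).tolist(),
        "centroid_xy": list(geometry.centroid),
        "reference_angle_rad": float(geometry.reference_angle),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_contours(path: str | Path):
    from .regions import MyocardialGeometry

    d = json.loads(Path(path).read_text())
    return MyocardialGeometry(
        np.asarray(d["endo_contour_xy"], dtype=float),
        np.asarray(d["epi_contour_xy"], dtype=float),
        tuple(d["centroid_xy"]),
        d["reference_angle_rad"],
    )
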