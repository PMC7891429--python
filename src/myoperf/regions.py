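"""Myocardial geometry: annulus masks, offset bands, AHA sectoring, T1 lookup.

Coordinate convention (fixed for reproducible rasterization): 0-based pixel
indices, pixel centers at integer coordinates, contour vertices as
``(x, y) = (col, row)``.  Angles are measured about the centroid,
counterclockwise in *anatomical* orientation, i.e. with the image y-axis
flipped: ``theta = atan2(centroid_row - row, col - centroid_col)``, so
``theta = pi/2`` points "up" in the displayed image.  Sector 1 starts at
``reference_angle`` (the anterior RV-insertion direction) and sectors
advance counterclockwise; for six sectors these are the mid-ventricular
AHA segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely import contains_xy
from shapely.geometry import LineString, Polygon

from .errors import GeometryError, InputError

__all__ = [
    "AHA_MID_SEGMENT_NAMES",
    "MyocardialGeometry",
    "T1Assignment",
    "build_annulus_mask",
    "offset_contours",
    "sectorize",
    "sector_t1_means",
    "build_t1_assignment",
]

#: Mid-ventricular AHA segment names, counterclockwise from the anterior
#: RV insertion (AHA segments 7-12).
AHA_MID_SEGMENT_NAMES = (
    "anterior",
    "anteroseptal",
    "inferoseptal",
    "inferior",
    "inferolateral",
    "anterolateral",
)


@dataclass
class MyocardialGeometry:
    """Endo-/epicardial contours of a mid-ventricular short-axis slice."""

    endo_contour: np.ndarray
    epi_contour: np.ndarray
    centroid: tuple[float, float] | None = None
    reference_angle: float = np.pi / 2

    def __post_init__(self) -> None:
        self.endo_contour = np.asarray(self.endo_contour, dtype=float)
        self.epi_contour = np.asarray(self.epi_contour, dtype=float)
        for name, c in (("endo", self.endo_contour), ("epi", self.epi_contour)):
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
                raise GeometryError(f"{name} contour must be (N>=3, 2) (x, y) vertices")
        if self.centroid is None:
            poly = Polygon(self.epi_contour)
            self.centroid = (poly.centroid.x, poly.centroid.y)

    def polygons(self) -> tuple[Polygon, Polygon]:
        endo = Polygon(self.endo_contour)
        epi = Polygon(self.epi_contour)
        if not endo.is_valid or not epi.is_valid:
            raise GeometryError("contours must be simple (non-self-intersecting)")
        return endo, epi


def _pixel_angles(shape, centroid):
    """Anatomical (y-up) angle of every pixel center about the centroid."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx, cy = centroid
    return np.arctan2(cy - rows, cols - cx)


def build_annulus_mask(geom: MyocardialGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Boolean myocardium mask: pixel centers inside epi and outside endo."""
    endo, epi = geom.polygons()
    if not epi.contains(endo):
        raise GeometryError("endocardial contour must lie strictly inside the epicardial contour")
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = cols.ravel().astype(float)
    y = rows.ravel().astype(float)
    inside_epi = contains_xy(epi, x, y).reshape(shape)
    inside_endo = contains_xy(endo, x, y).reshape(shape)
    mask = inside_epi & ~inside_endo
    if not mask.any():
        raise GeometryError("annulus mask is empty; degenerate contours")
    return mask


def _radial_profile(polygon_xy: np.ndarray, centroid, thetas: np.ndarray) -> np.ndarray:
    """Radius of a (star-shaped) contour along rays at anatomical angles."""
    cx, cy = centroid
    ring = LineString(np.vstack([polygon_xy, polygon_xy[:1]]))
    span = 4.0 * max(np.abs(polygon_xy - [cx, cy]).max(), 1.0)
    radii = np.empty(len(thetas))
    for i, th in enumerate(thetas):
        # anatomical angle -> image direction (y flipped)
        ray = LineString([(cx, cy), (cx + span * np.cos(th), cy - span * np.sin(th))])
        hit = ring.intersection(ray)
        if hit.is_empty:
            raise GeometryError("ray from centroid misses the contour")
        pts = getattr(hit, "geoms", [hit])
        radii[i] = max(np.hypot(p.x - cx, p.y - cy) for p in pts if p.geom_type == "Point")
    return radii


def offset_contours(
    geom: MyocardialGeometry,
    shape: tuple[int, int],
    fraction: float = 0.25,
    n_rays: int = 720,
) -> np.ndarray:
    """Mid-wall measurement band: erode the annulus from both borders.

    Along each radial ray from the centroid only the band from
    ``endo + fraction * wall`` to ``epi - fraction * wall`` is kept, where
    ``wall`` is the local wall thickness.  An offset of 25% from the drawn
    contours makes regional T1 means robust against partial-volume pixels
    at the blood and epicardial-fat interfaces; the band is used for T1
    measurement only, never for the perfusion analysis itself.
    """
    if not 0 <= fraction < 0.5:
        raise InputError(f"fraction must be in [0, 0.5), got {fraction}")
    annulus = build_annulus_mask(geom, shape)
    if fraction == 0:
        return annulus

    thetas = np.linspace(-np.pi, np.pi, n_rays, endpoint=False)
    r_endo = _radial_profile(geom.endo_contour, geom.centroid, thetas)
    r_epi = _radial_profile(geom.epi_contour, geom.centroid, thetas)
    wall = r_epi - r_endo
    thin = (1.0 - 2.0 * fraction) * wall < 2.0
    if thin.any():
        warnings.warn(
            f"{int(thin.sum())}/{n_rays} rays have a post-offset band thinner "
            "than 2 px; those rays are excluded",
            RuntimeWarning,
        )

    cx, cy = geom.centroid
    rows, cols = np.nonzero(annulus)
    px_theta = np.arctan2(cy - rows, cols - cx)
    px_r = np.hypot(cols - cx, rows - cy)

    # periodic interpolation of the radial profiles
    def interp_profile(profile, theta):
        ext_t = np.concatenate([thetas, [np.pi]])
        ext_p = np.concatenate([profile, [profile[0]]])
        return np.interp(theta, ext_t, ext_p)

    re_px = interp_profile(r_endo, px_theta)
    rE_px = interp_profile(r_epi, px_theta)
    w_px = rE_px - re_px
    keep = (
        (px_r >= re_px + fraction * w_px)
        & (px_r <= rE_px - fraction * w_px)
        & ((1.0 - 2.0 * fraction) * w_px >= 2.0)
    )
    band = np.zeros(shape, dtype=bool)
    band[rows[keep], cols[keep]] = True
    return band


def sectorize(
    geom: MyocardialGeometry, n_sectors: int, shape: tuple[int, int]
) -> np.ndarray:
    """Equal-angle sector labels (1..n) about the centroid, full image.

    Sector 1 starts at ``reference_angle`` and sectors advance
    counterclockwise; 12/18/24 sectors nest exactly inside the 6 AHA
    segments (label collapse ``(s-1) // (n/6) + 1``).  Angular ties at
    sector boundaries go to the lower-index sector.  Callers intersect the
    label map with a myocardial mask.
    """
    if n_sectors not in (1, 6, 12, 18, 24):
        raise InputError(f"n_sectors must be one of 1, 6, 12, 18, 24, got {n_sectors}")
    if n_sectors == 1:
        return np.ones(shape, dtype=int)
    theta = _pixel_angles(shape, geom.centroid)
    rel = np.mod(theta - geom.reference_angle, 2.0 * np.pi)
    u = rel / (2.0 * np.pi)  # in [0, 1)
    # hierarchical binning: AHA segment first, then equal subdivisions,
    # so finer divisions nest exactly inside the 6 segments
    s6 = np.floor(u * 6.0)
    exact = (u > 0) & (u * 6.0 == s6)
    s6[exact] -= 1  # boundary ties to the lower sector
    s6 = np.clip(s6, 0, 5).astype(int)
    m = n_sectors // 6
    if m == 1:
        return s6 + 1
    frac = u * 6.0 - s6
    sub = np.floor(frac * m)
    exact_sub = (frac > 0) & (frac * m == sub)
    sub[exact_sub] -= 1
    sub = np.clip(sub, 0, m - 1).astype(int)
    return s6 * m + sub + 1


def sector_t1_means(
    t1_map: np.ndarray,
    sector_labels: np.ndarray,
    measurement_mask: np.ndarray,
) -> np.ndarray:
    """Arithmetic mean native T1 per sector over the measurement band.

    Returns an array of length ``n_sectors`` (1-based sectors at index
    ``s - 1``); sectors with an empty intersection yield NaN with a warning.
    """
    t1_map = np.asarray(t1_map, dtype=float)
    sector_labels = np.asarray(sector_labels)
    measurement_mask = np.asarray(measurement_mask, dtype=bool)
    if not (t1_map.shape == sector_labels.shape == measurement_mask.shape):
        raise InputError("t1_map, labels and mask must share one shape")
    n = int(sector_labels[measurement_mask].max()) if measurement_mask.any() else 0
    if n == 0:
        raise InputError("measurement mask is empty")
    means = np.full(n, np.nan)
    for s in range(1, n + 1):
        sel = measurement_mask & (sector_labels == s)
        if not sel.any():
            warnings.warn(f"sector {s} does not intersect the measurement mask", RuntimeWarning)
            continue
        means[s - 1] = float(np.nanmean(t1_map[sel]))
    return means


@dataclass
class T1Assignment:
    """Per-pixel native T1 choice used for nonlinearity correction.

    mode
        ``none``            : no correction (baseline subtraction only);
        ``global_scalar``   : one myocardial T1 for every pixel;
        ``sectoral``        : one T1 per angular sector (6/12/18/24);
        ``population_average``: configured cohort-mean scalars;
        ``pixel_map``       : per-pixel T1 from the subject's native map.
    """

    mode: str
    blood_t1: float
    myo_t1_per_pixel: np.ndarray | None = None
    sector_count: int = 1
    source_phase: str = "diastole"
    meta: dict = field(default_factory=dict)

    _MODES = ("none", "global_scalar", "sectoral", "population_average", "pixel_map")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise InputError(f"unknown T1 assignment mode {self.mode!r}")
        if self.mode != "none":
            if not self.blood_t1 > 0:
                raise InputError("blood_t1 must be > 0")
            if self.myo_t1_per_pixel is None:
                raise InputError(f"mode {self.mode!r} requires a per-pixel myocardial T1 map")

    @property
    def corrected(self) -> bool:
        return self.mode != "none"


#: Cohort-mean native T1 values (seconds) per cardiac phase, used by the
#: population_average mode when no subject-specific map is available.
POPULATION_T1 = {
    "diastole": {"blood": 1.891, "myocardium": 1.259},
    "systole": {"blood": 1.897, "myocardium": 1.249},
}


def build_t1_assignment(
    mode: str,
    *,
    shape: tuple[int, int] | None = None,
    geometry: MyocardialGeometry | None = None,
    t1_map: np.ndarray | None = None,
    blood_t1: float | None = None,
    myo_t1: float | None = None,
    n_sectors: int = 1,
    phase: str = "diastole",
    measurement_fraction: float = 0.25,
    population_t1: dict | None = None,
) -> T1Assignment:
    """Construct a :class:`T1Assignment` for one pipeline variant.

    * ``none``: no inputs needed.
    * ``global_scalar``: ``blood_t1`` and either ``myo_t1`` or (``t1_map`` +
      ``geometry``) to measure the global myocardial mean over the offset
      band.
    * ``sectoral``: ``t1_map`` + ``geometry`` + ``n_sectors``; sector means
      are measured over the 25%-offset band and broadcast to the full
      annulus.
    * ``population_average``: configured cohort means (per phase).
    * ``pixel_map``: ``t1_map`` + ``geometry``; per-pixel lookup.
    """
    if mode == "none":
        return T1Assignment("none", blood_t1=float("nan"), source_phase=phase)

    if mode == "population_average":
        pop = (population_t1 or POPULATION_T1)[phase]
        blood, myo = pop["blood"], pop["myocardium"]
        if shape is None or geometry is None:
            raise InputError("population_average needs shape and geometry")
        annulus = build_annulus_mask(geometry, shape)
        t1_px = np.where(annulus, myo, np.nan)
        return T1Assignment("population_average", blood, t1_px, 1, phase)

    if geometry is None or shape is None:
        raise InputError(f"mode {mode!r} requires geometry and shape")
    annulus = build_annulus_mask(geometry, shape)

    if mode == "global_scalar":
        if blood_t1 is None:
            raise InputError("global_scalar requires blood_t1")
        if myo_t1 is None:
            if t1_map is None:
                raise InputError("global_scalar requires myo_t1 or t1_map")
            band = offset_contours(geometry, shape, measurement_fraction)
            myo_t1 = float(np.nanmean(np.asarray(t1_map, float)[band]))
        t1_px = np.where(annulus, myo_t1, np.nan)
        return T1Assignment("global_scalar", float(blood_t1), t1_px, 1, phase)

    if t1_map is None:
        raise InputError(f"mode {mode!r} requires a native t1_map")
    t1_map = np.asarray(t1_map, dtype=float)
    if blood_t1 is None:
        raise InputError(f"mode {mode!r} requires blood_t1")

    if mode == "pixel_map":
        t1_px = np.where(annulus, t1_map, np.nan)
        return T1Assignment("pixel_map", float(blood_t1), t1_px, 1, phase)

    # sectoral
    labels = sectorize(geometry, n_sectors, shape)
    band = offset_contours(geometry, shape, measurement_fraction)
    means = sector_t1_means(t1_map, labels, band)
    t1_px = np.full(shape, np.nan)
    for s in range(1, n_sectors + 1):
        t1_px[annulus & (labels == s)] = means[s - 1]
    return T1Assignment("sectoral", float(blood_t1), t1_px, n_sectors, phase)
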