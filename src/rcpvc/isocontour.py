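"""Operator-independent threshold-isocontour lesion measurement.

The measurement runs on the axial slice holding the lesion maximum: the
isocontour at a fixed fraction of that maximum defines both the uptake ROI
and the circle-equivalent section of a spherical metabolic volume.  Lesion
uptake is the mean concentration inside the isocontour; background is the
mean over four circular ROIs placed around the lesion on the same slice;
their ratio is the measured lesion-to-background ratio L/B_m.  All steps are
deterministic (fixed tie-breaks), so repeated measurement of the same volume
is bit-identical, and every output is invariant under a positive rescaling
of the volume because the threshold is relative to the maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure as _skmeasure

from .phantom import VolumeImage

__all__ = [
    "LesionMeasurement",
    "ThresholdEvaluation",
    "IsocontourROI",
    "find_lesion_max",
    "isocontour_roi",
    "isocontour_roi_3d",
    "measure_lesion",
    "measure_background",
    "compute_lbm",
    "measure_at_threshold",
    "optimize_threshold",
    "percent_diameter_difference",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.60
#: In-plane refinement factor for sub-voxel isocontours.
DEFAULT_UPSAMPLE = 4
#: Radius of the small disk averaged around the refined peak to define the
#: "maximum uptake" (SUVpeak-style): robust to noise on single voxels and to
#: where the lesion falls relative to voxel centers.
DEFAULT_PEAK_RADIUS_MM = 2.35


@dataclass
class IsocontourROI:
    """Connected 2-D region >= threshold x max on the (refined) max slice.

    The mask lives on the axial slice bilinearly refined by ``upsample`` in
    each in-plane direction (``upsample=1`` is the native voxel grid), so
    the isocontour area varies smoothly with lesion size instead of jumping
    by whole-voxel increments.  ``plane`` holds the refined slice values the
    mask indexes into; ``pixel_size_mm`` is the refined (dy, dx).
    """

    mask: np.ndarray  # 2-D boolean, refined grid
    slice_index: int
    threshold_fraction: float
    pixel_size_mm: tuple[float, float]
    plane: np.ndarray
    upsample: int = 1
    touches_border: bool = False

    def native_mask(self) -> np.ndarray:
        """Lesion footprint on the native voxel grid (any-overlap rule)."""
        if self.upsample == 1:
            return self.mask
        u = self.upsample
        n0, n1 = self.mask.shape[0] // u, self.mask.shape[1] // u
        return self.mask.reshape(n0, u, n1, u).any(axis=(1, 3))


@dataclass
class LesionMeasurement:
    """Per-lesion uptake / volume record produced by the isocontour technique.

    Attributes
    ----------
    c_thr : mean concentration inside the isocontour (MBq/mL).
    b_m : measured background concentration (MBq/mL), or nan if skipped.
    lbm : measured lesion-to-background ratio ``c_thr / b_m``.
    d_thr_mm : circle-equivalent diameter of the isocontour area.
    v_thr_ml : spherical metabolic volume (pi/6) d^3 built on that diameter.
    """

    threshold_fraction: float
    max_value: float
    max_location: tuple[int, int, int]
    c_thr: float
    area_mm2: float
    d_thr_mm: float
    v_thr_ml: float
    b_m: float = math.nan
    lbm: float = math.nan
    flags: list[str] = field(default_factory=list)
    lesion_id: int | str | None = None

    def as_record(self) -> dict:
        return {
            "lesion_id": self.lesion_id,
            "threshold": self.threshold_fraction,
            "C_thr": self.c_thr,
            "B_m": self.b_m,
            "LBm": self.lbm,
            "d_thr_mm": self.d_thr_mm,
            "V_thr_mL": self.v_thr_ml,
            "flags": ";".join(self.flags),
        }


@dataclass
class ThresholdEvaluation:
    """Per-threshold table of actual vs measured sphere diameters."""

    threshold_fraction: float
    d_actual_mm: list[float]
    d_measured_mm: list[float]
    pct_diff: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pct_diff:
            self.pct_diff = [
                percent_diameter_difference(a, m)
                for a, m in zip(self.d_actual_mm, self.d_measured_mm)
            ]

    @property
    def all_nonnegative(self) -> bool:
        return all(p >= 0 for p in self.pct_diff)

    @property
    def mean_abs_diff(self) -> float:
        return float(np.mean(np.abs(self.pct_diff)))


def find_lesion_max(
    volume: VolumeImage,
    seed_point: Sequence[int],
    search_radius_mm: float = 20.0,
) -> tuple[tuple[int, int, int], float]:
    """Locate the hottest lesion voxel within a ball around an approximate seed.

    The axial slice is chosen first as the one with the highest total
    activity inside the search ball (a noise-robust stand-in for "the image
    containing the maximum uptake": for any axially symmetric lesion it is
    the central slice, and single-voxel noise cannot move it), then the
    hottest voxel on that slice within the ball is returned.  Ties break to
    the lowest flat index (C order), so the result is unique.
    """
    if search_radius_mm <= 0:
        raise ValueError("search_radius_mm must be positive")
    seed = np.asarray(seed_point, dtype=int)
    if np.any(seed < 0) or np.any(seed >= np.asarray(volume.shape)):
        raise ValueError(f"seed point {tuple(seed)} outside volume {volume.shape}")
    axes = [
        (np.arange(n) - s) * v
        for n, s, v in zip(volume.shape, seed, volume.voxel_size_mm)
    ]
    dist2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    in_ball = dist2 <= search_radius_mm**2
    if not np.any(in_ball):
        raise ValueError("empty search region")
    in_ball_values = np.where(in_ball, volume.values, 0.0)
    k = int(np.argmax(in_ball_values.sum(axis=(1, 2))))
    masked = np.where(in_ball[k], volume.values[k], -np.inf)
    flat = int(np.argmax(masked))  # first maximum in C order
    i, j = np.unravel_index(flat, masked.shape)
    return (k, int(i), int(j)), float(volume.values[k, i, j])


def _axial_peak_plane(
    volume: VolumeImage, k: int, i: int, j: int, window: int = 4
) -> np.ndarray:
    """Axial slice through the lesion's sub-slice activity peak.

    The axial position of the lesion is localized to sub-slice precision by
    a parabolic fit to local slice sums (a small in-plane window around the
    maximum), and the measurement plane is cubic-interpolated between slices
    at that position.  This removes the dependence of the measured
    cross-section on where the lesion center falls between slice centers.
    """
    from scipy.interpolate import CubicSpline

    nz = volume.shape[0]
    lo, hi = max(k - 3, 0), min(k + 4, nz)
    if hi - lo < 4:
        return volume.values[k]
    sub = volume.values[lo:hi]
    win = sub[
        :,
        max(i - window, 0) : i + window + 1,
        max(j - window, 0) : j + window + 1,
    ]
    s = win.sum(axis=(1, 2))
    km = int(np.argmax(s))
    dz = 0.0
    if 0 < km < len(s) - 1:
        denom = s[km - 1] - 2.0 * s[km] + s[km + 1]
        if denom < 0:
            dz = float(np.clip(0.5 * (s[km - 1] - s[km + 1]) / denom, -0.5, 0.5))
    z_star = lo + km + dz
    spline = CubicSpline(np.arange(lo, hi, dtype=float), sub, axis=0)
    return np.clip(spline(z_star), 0.0, None)


def isocontour_roi(
    volume: VolumeImage,
    max_location: Sequence[int],
    threshold_fraction: float = DEFAULT_THRESHOLD,
    upsample: int = DEFAULT_UPSAMPLE,
    peak_radius_mm: float = DEFAULT_PEAK_RADIUS_MM,
    axial_refine: bool = True,
) -> IsocontourROI:
    """4-connected component >= threshold x max on the axial max slice.

    The slice is refined ``upsample``-fold in-plane by cubic-spline
    interpolation first (blurred PET fields are smooth, so the spline tracks
    the underlying profile almost independently of where voxel centers fall
    relative to the lesion), and the threshold level is set from the mean of
    a small disk (radius ``peak_radius_mm``) around the refined local peak —
    a noise- and sampling-robust estimate of the maximum uptake.  This gives
    a sub-voxel isocontour whose circle-equivalent diameter varies
    continuously with lesion size instead of jumping by whole-voxel
    increments.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    k, i, j = (int(v) for v in max_location)
    plane = (
        _axial_peak_plane(volume, k, i, j) if axial_refine else volume.values[k]
    )
    dz, dy, dx = volume.voxel_size_mm
    if upsample > 1:
        fine = np.clip(
            ndimage.zoom(plane, upsample, order=3, mode="nearest", grid_mode=True),
            0.0,
            None,
        )
        # refined local peak: within one native voxel of the maximum voxel
        lo_i, hi_i = max(i - 1, 0) * upsample, min(i + 2, plane.shape[0]) * upsample
        lo_j, hi_j = max(j - 1, 0) * upsample, min(j + 2, plane.shape[1]) * upsample
        cell = fine[lo_i:hi_i, lo_j:hi_j]
        di, dj = np.unravel_index(int(np.argmax(cell)), cell.shape)
        si, sj = lo_i + di, lo_j + dj
    else:
        fine, si, sj = plane, i, j
    if peak_radius_mm > 0:
        ii = np.arange(fine.shape[0])[:, None]
        jj = np.arange(fine.shape[1])[None, :]
        disk = ((ii - si) * dy / upsample) ** 2 + (
            (jj - sj) * dx / upsample
        ) ** 2 <= peak_radius_mm**2
        peak = float(fine[disk].mean())
    else:
        peak = float(fine[si, sj])
    level = threshold_fraction * peak
    labels = _skmeasure.label(fine >= level, connectivity=1)
    mask = labels == labels[si, sj]
    touches = bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    return IsocontourROI(
        mask,
        k,
        threshold_fraction,
        (dy / upsample, dx / upsample),
        fine,
        upsample,
        touches,
    )


def isocontour_roi_3d(
    volume: VolumeImage,
    max_location: Sequence[int],
    threshold_fraction: float = DEFAULT_THRESHOLD,
) -> np.ndarray:
    """3-D 6-connected variant (not the default measurement path)."""
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    k, i, j = (int(v) for v in max_location)
    level = threshold_fraction * volume.values[k, i, j]
    labels = _skmeasure.label(volume.values >= level, connectivity=1)
    return labels == labels[k, i, j]


def measure_lesion(
    volume: VolumeImage,
    roi: IsocontourROI,
) -> LesionMeasurement:
    """Uptake and metabolic-volume part of the measurement (no background).

    ``c_thr`` is the mean inside the isocontour; the circle-equivalent
    diameter is ``2 sqrt(area / pi)`` (kept full-precision; round only for
    tabulation); the metabolic volume is the sphere built on it.
    """
    if not np.any(roi.mask):
        raise ValueError("empty isocontour mask")
    plane = roi.plane
    c_thr = float(plane[roi.mask].mean())
    py, px = roi.pixel_size_mm
    area = float(roi.mask.sum()) * py * px
    d_thr = 2.0 * math.sqrt(area / math.pi)
    v_thr_ml = math.pi / 6.0 * d_thr**3 / 1000.0  # mm^3 -> mL
    flat = int(np.argmax(np.where(roi.mask, plane, -np.inf)))
    i, j = np.unravel_index(flat, plane.shape)
    flags = ["truncated"] if roi.touches_border else []
    return LesionMeasurement(
        threshold_fraction=roi.threshold_fraction,
        max_value=float(plane[i, j]),
        max_location=(roi.slice_index, int(i) // roi.upsample, int(j) // roi.upsample),
        c_thr=c_thr,
        area_mm2=area,
        d_thr_mm=d_thr,
        v_thr_ml=v_thr_ml,
        flags=flags,
    )


def measure_background(
    volume: VolumeImage,
    max_location: Sequence[int],
    lesion_mask: np.ndarray,
    n_rois: int = 4,
    roi_diameter_mm: float = 15.0,
    standoff_mm: float | None = None,
    d_thr_mm: float | None = None,
    clearance_mm: float = 8.0,
) -> float:
    """Mean concentration over circular background ROIs around the lesion.

    ``n_rois`` circular 2-D ROIs are placed at equal angular spacing on the
    max slice, their centers ``standoff_mm`` from the lesion centroid.  By
    default the standoff is chosen so the ROI inner edge clears the lesion
    radius by ``clearance_mm`` (a couple of PSF widths), keeping the blurred
    spill-out flank of the lesion out of the background sample.  If any ROI
    overlaps the lesion mask or falls outside the slice, the ring is rotated
    in small steps; if no rotation works an error asks for a manual offset
    (e.g. an adjacent high-uptake organ in the way).
    """
    k = int(max_location[0])
    plane = volume.values[k]
    dz, dy, dx = volume.voxel_size_mm
    mask = np.asarray(lesion_mask, dtype=bool)
    ii, jj = np.nonzero(mask)
    if ii.size == 0:
        raise ValueError("empty lesion mask")
    centroid = np.array([ii.mean() * dy, jj.mean() * dx])
    if standoff_mm is None:
        if d_thr_mm is None:
            d_thr_mm = 2.0 * math.sqrt(mask.sum() * dy * dx / math.pi)
        standoff_mm = d_thr_mm / 2.0 + clearance_mm + roi_diameter_mm / 2.0
    yy = np.arange(plane.shape[0])[:, None] * dy
    xx = np.arange(plane.shape[1])[None, :] * dx
    r2 = (roi_diameter_mm / 2.0) ** 2

    for rotation in np.deg2rad(np.arange(0.0, 90.0, 15.0)):
        angles = rotation + np.arange(n_rois) * 2.0 * np.pi / n_rois
        union = np.zeros_like(mask)
        ok = True
        for ang in angles:
            cy = centroid[0] + standoff_mm * math.sin(ang)
            cx = centroid[1] + standoff_mm * math.cos(ang)
            roi = (yy - cy) ** 2 + (xx - cx) ** 2 <= r2
            if not roi.any():
                ok = False
                break
            edge = (
                cy - roi_diameter_mm / 2 < 0
                or cx - roi_diameter_mm / 2 < 0
                or cy + roi_diameter_mm / 2 > plane.shape[0] * dy
                or cx + roi_diameter_mm / 2 > plane.shape[1] * dx
            )
            if edge or (roi & mask).any():
                ok = False
                break
            union |= roi
        if ok:
            return float(plane[union].mean())
    raise ValueError(
        "could not place background ROIs clear of the lesion; "
        "offset them manually (exclude adjacent high-uptake structures)"
    )


def compute_lbm(c_thr: float, b_m: float) -> tuple[float, list[str]]:
    """Measured lesion-to-background ratio, flagging cold 'lesions'."""
    if b_m <= 0:
        raise ValueError("background concentration must be positive")
    lbm = c_thr / b_m
    flags = [] if lbm >= 1.0 else ["lesion not hotter than background"]
    return lbm, flags


def measure_at_threshold(
    volume: VolumeImage,
    seed_point: Sequence[int],
    threshold_fraction: float = DEFAULT_THRESHOLD,
    search_radius_mm: float = 20.0,
    lesion_id: int | str | None = None,
    background: bool = True,
    upsample: int = DEFAULT_UPSAMPLE,
    **background_kwargs,
) -> LesionMeasurement:
    """Full pipeline: locate max, isocontour, uptake, background, L/B_m."""
    loc, _ = find_lesion_max(volume, seed_point, search_radius_mm)
    roi = isocontour_roi(volume, loc, threshold_fraction, upsample)
    m = measure_lesion(volume, roi)
    m.lesion_id = lesion_id
    if background:
        background_kwargs.setdefault("d_thr_mm", m.d_thr_mm)
        m.b_m = measure_background(volume, loc, roi.native_mask(), **background_kwargs)
        m.lbm, flags = compute_lbm(m.c_thr, m.b_m)
        m.flags.extend(flags)
    return m


def percent_diameter_difference(d_actual_mm: float, d_measured_mm: float) -> float:
    """100 (d_actual - d_measured) / d_actual; negative = oversized contour."""
    if d_actual_mm <= 0:
        raise ValueError("actual diameter must be positive")
    return 100.0 * (d_actual_mm - d_measured_mm) / d_actual_mm


def optimize_threshold(
    evaluations: Sequence[ThresholdEvaluation],
) -> tuple[float, list[str]]:
    """Pick the threshold whose contours best match actual sphere diameters.

    Among thresholds whose per-sphere mean percentage differences are all
    non-negative (contours never larger than the sphere, so no background is
    swept in), returns the one with the smallest mean absolute difference.
    If no threshold qualifies, returns the overall smallest-|diff| threshold
    with a warning flag.
    """
    if not evaluations:
        raise ValueError("no threshold evaluations supplied")
    qualified = [e for e in evaluations if e.all_nonnegative]
    if qualified:
        best = min(qualified, key=lambda e: e.mean_abs_diff)
        return best.threshold_fraction, []
    best = min(evaluations, key=lambda e: e.mean_abs_diff)
    return best.threshold_fraction, ["no threshold with all-nonnegative differences"]
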