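"""Recovery-coefficient calibration from hot-sphere-in-hot-background data.

An RC sample is the ratio of the measured lesion-to-background ratio
(L/B_m, from the threshold-isocontour technique) to the gold-standard ratio
(L/B_GS, from dose-calibrator concentrations).  Samples taken across
background levels are grouped per sphere, fitted with the three-parameter
hyperbola ``RC(x) = a - b / (x + c)`` in x = L/B_m, and the per-diameter
curves assembled into an RC surface indexed by *measured* isocontour
diameter — the defining choice of the method: every coordinate used for
correction is itself a PET measurement, never a quantity that would require
knowing the true lesion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit

from . import isocontour as _iso
from . import phantom as _ph

__all__ = [
    "RCSample",
    "RCCurve",
    "RCSurface",
    "compute_lb_gs",
    "compute_rc",
    "fit_rc_curve",
    "build_rc_surface",
    "calibrate_from_simulation",
    "LBM_RANGE",
    "SUPER_RECOVERY_LIMIT",
]

#: Global L/B_m validity box of the calibration.
LBM_RANGE = (2.0, 30.0)
#: RC above this is flagged as implausible super-recovery.
SUPER_RECOVERY_LIMIT = 1.1

FORMAT_VERSION = 1


def compute_lb_gs(
    c_gs_sphere: float,
    c_gs_background: float,
    u_sphere: float | None = None,
    u_background: float | None = None,
) -> tuple[float, float | None]:
    """Gold-standard lesion-to-background ratio from calibrator concentrations.

    Returns ``(lb_gs, uncertainty)``; the uncertainty (None when the inputs
    carry none) propagates the two relative errors in quadrature.
    """
    if c_gs_sphere <= 0 or c_gs_background <= 0:
        raise ValueError("gold-standard concentrations must be positive")
    lb = c_gs_sphere / c_gs_background
    if u_sphere is None or u_background is None:
        return lb, None
    rel = math.hypot(u_sphere / c_gs_sphere, u_background / c_gs_background)
    return lb, lb * rel


def compute_rc(lbm: float, lb_gs: float) -> tuple[float, list[str]]:
    """RC = L/B_m / L/B_GS, with a super-recovery plausibility flag."""
    if lb_gs <= 0:
        raise ValueError("gold-standard ratio must be positive")
    rc = lbm / lb_gs
    flags = ["super-recovery"] if rc > SUPER_RECOVERY_LIMIT else []
    return rc, flags


@dataclass
class RCSample:
    """One calibration point: a sphere measured at one background level."""

    d_actual_mm: float
    d_measured_mm: float
    lbm: float
    lb_gs: float
    rc: float = math.nan
    rc_uncertainty: float | None = None

    def __post_init__(self) -> None:
        if math.isnan(self.rc):
            self.rc, _ = compute_rc(self.lbm, self.lb_gs)


def _hyperbola(x, a, b, c):
    return a - b / (x + c)


@dataclass
class RCCurve:
    """Per-sphere hyperbolic recovery curve RC(x) = a - b/(x + c).

    ``diameter_mm`` is the curve's nominal measured-diameter label (mean
    isocontour diameter over its calibration samples).  Because the
    percentage-of-maximum contour of one and the same object measures larger
    at low contrast, the curve also carries its measured-diameter trend
    versus L/B_m (``d_knots``): ``d_at(lbm)`` returns the isocontour
    diameter this calibration object shows at a given contrast, which is the
    coordinate used to place correction queries between curves.
    """

    diameter_mm: float
    a: float
    b: float
    c: float
    r_squared: float
    lbm_range: tuple[float, float]
    degenerate: bool = False
    d_knots: tuple[tuple[float, ...], tuple[float, ...]] | None = None

    def __call__(self, lbm: float | np.ndarray) -> float | np.ndarray:
        return _hyperbola(np.asarray(lbm, dtype=float), self.a, self.b, self.c)

    def d_at(self, lbm: float) -> float:
        """Measured isocontour diameter of this calibration object at L/B_m."""
        if not self.d_knots:
            return self.diameter_mm
        x, d = self.d_knots
        return float(np.interp(lbm, x, d))

    def to_dict(self) -> dict:
        out = {
            "diameter_mm": float(self.diameter_mm),
            "a": float(self.a),
            "b": float(self.b),
            "c": float(self.c),
            "r_squared": float(self.r_squared),
            "lbm_range": [float(v) for v in self.lbm_range],
            "degenerate": bool(self.degenerate),
        }
        if self.d_knots:
            out["d_knots"] = [list(map(float, arr)) for arr in self.d_knots]
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RCCurve":
        knots = d.get("d_knots")
        return cls(
            d["diameter_mm"],
            d["a"],
            d["b"],
            d["c"],
            d["r_squared"],
            tuple(d["lbm_range"]),
            d.get("degenerate", False),
            tuple(tuple(arr) for arr in knots) if knots else None,
        )


def fit_rc_curve(samples: Sequence[RCSample]) -> RCCurve:
    """Least-squares fit of the three-parameter hyperbola to RC samples.

    Initialization is deterministic: ``a0`` = RC at the largest sampled
    L/B_m (the saturation side), ``c0 = 1``, ``b0`` from the two extreme
    samples; ``c`` is bounded so the pole ``x = -c`` stays below the
    smallest sampled L/B_m.  The sign of ``b`` is free, so the curve follows
    whichever monotone trend the samples show.  Samples carrying
    uncertainties weight the fit.  Near-constant samples short-circuit to a
    flagged constant curve (b = 0).
    """
    if len(samples) < 4:
        raise ValueError("need at least 4 samples spanning the L/B_m range")
    x = np.array([s.lbm for s in samples], dtype=float)
    y = np.array([s.rc for s in samples], dtype=float)
    d_all = np.array([s.d_measured_mm for s in samples], dtype=float)
    order = np.argsort(x)
    x, y, d_all = x[order], y[order], d_all[order]
    d_meas = float(d_all.mean())
    d_knots = (tuple(map(float, x)), tuple(map(float, d_all)))
    lbm_range = (float(x.min()), float(x.max()))

    if np.ptp(y) < 1e-9:  # constant samples: hyperbola is unidentifiable
        return RCCurve(d_meas, float(y.mean()), 0.0, 1.0, 1.0, lbm_range, True, d_knots)

    c_min_init = -float(x.min()) + 1e-3
    a0 = float(np.clip(y[-1], 1e-6, 2.0))  # saturation side: value at largest L/B_m
    c0 = max(1.0, c_min_init + 1.0)
    b0 = (a0 - y[0]) * (x[0] + c0)
    if abs(b0) < 1e-3:
        b0 = 1e-3
    sigma = None
    if all(s.rc_uncertainty is not None for s in samples):
        sigma = np.array([s.rc_uncertainty for s in samples], dtype=float)[order]
        sigma = np.where(sigma > 0, sigma, sigma[sigma > 0].min())
    c_min = -float(x.min()) + 1e-3  # pole strictly below the data range
    try:
        popt, _ = curve_fit(
            _hyperbola,
            x,
            y,
            p0=(a0, b0, c0),
            sigma=sigma,
            bounds=((0.0, -np.inf, c_min), (2.0, np.inf, np.inf)),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"hyperbolic fit did not converge for curve at {d_meas:.1f} mm "
            f"({len(samples)} samples, L/B_m {lbm_range})"
        ) from err
    resid = y - _hyperbola(x, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return RCCurve(d_meas, *(float(p) for p in popt), r2, lbm_range, False, d_knots)


@dataclass
class RCSurface:
    """RC as a function of (L/B_m, measured diameter): the correction lookup.

    Evaluation interpolates linearly in diameter between the two bracketing
    per-sphere curves; queries outside the calibration box (L/B_m outside
    ``lbm_range``, diameter outside the calibrated diameters) are clamped to
    the box edge and flagged rather than extrapolated.
    """

    curves: list[RCCurve]
    lbm_range: tuple[float, float] = LBM_RANGE
    threshold_fraction: float = _iso.DEFAULT_THRESHOLD
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.curves = sorted(self.curves, key=lambda c: c.diameter_mm)
        d = [c.diameter_mm for c in self.curves]
        if len(set(d)) != len(d):
            raise ValueError("curve diameters must be distinct")

    @property
    def diameter_range(self) -> tuple[float, float]:
        return (self.curves[0].diameter_mm, self.curves[-1].diameter_mm)

    def evaluate(self, lbm: float, d_measured_mm: float) -> tuple[float, list[str]]:
        """RC at a query point, with clamping flags.

        The query's measured diameter is compared with the diameter each
        calibration curve itself measures at the query's L/B_m (the
        isocontour of one object is contrast-dependent, so the diameter
        coordinate must be taken at matched contrast); RC is then linearly
        interpolated between the two bracketing curves.
        """
        flags = []
        lo, hi = self.lbm_range
        if not lo <= lbm <= hi:
            flags.append("lbm_clamped")
            lbm = min(max(lbm, lo), hi)
        if len(self.curves) == 1:
            return float(self.curves[0](lbm)), flags
        diams = np.array([c.d_at(lbm) for c in self.curves])
        order = np.argsort(diams, kind="stable")
        diams = diams[order]
        values = np.array([float(self.curves[int(o)](lbm)) for o in order])
        if not diams[0] <= d_measured_mm <= diams[-1]:
            flags.append("diameter_clamped")
            d_measured_mm = min(max(d_measured_mm, diams[0]), diams[-1])
        if len(diams) >= 3 and np.all(np.diff(diams) > 0):
            # RC vs diameter is strongly convex between the small calibration
            # spheres; shape-preserving cubic avoids the systematic
            # under-recovery a chord (linear) interpolant gives there
            rc = float(PchipInterpolator(diams, values)(d_measured_mm))
        else:
            rc = float(np.interp(d_measured_mm, diams, values))
        return rc, flags

    def monotonicity_warnings(self, n_grid: int = 25) -> list[str]:
        """Check RC is nondecreasing in diameter at fixed L/B_m (quality check)."""
        out = []
        for lbm in np.linspace(*self.lbm_range, n_grid):
            vals = [float(c(lbm)) for c in self.curves]
            if np.any(np.diff(vals) < -1e-6):
                out.append(f"RC not nondecreasing in diameter at L/B_m={lbm:.1f}")
        return out

    # ---- persistence ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "threshold_fraction": float(self.threshold_fraction),
            "lbm_range": [float(v) for v in self.lbm_range],
            "curves": [c.to_dict() for c in self.curves],
            "warnings": list(self.warnings),
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RCSurface":
        if d.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported RC surface format: {d.get('format_version')}")
        return cls(
            [RCCurve.from_dict(c) for c in d["curves"]],
            tuple(d["lbm_range"]),
            d["threshold_fraction"],
            list(d.get("warnings", [])),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RCSurface":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_rc_surface(
    curves: Sequence[RCCurve],
    lbm_range: tuple[float, float] = LBM_RANGE,
    threshold_fraction: float = _iso.DEFAULT_THRESHOLD,
) -> RCSurface:
    """Assemble per-diameter curves into a correction surface."""
    if not curves:
        raise ValueError("no curves supplied")
    warnings = []
    if len(curves) == 1:
        warnings.append("single curve: surface degenerates to that curve")
    surface = RCSurface(list(curves), lbm_range, threshold_fraction, warnings)
    surface.warnings.extend(surface.monotonicity_warnings())
    return surface


# ---------------------------------------------------------------------------
# Simulation-driven calibration (the digital analogue of the phantom sessions)


def calibrate_from_simulation(
    lb_gs_levels: Sequence[float] = (
        2.5, 3.0, 3.6, 4.4, 5.6, 7.0, 9.0, 11.5, 14.5, 18.5, 23.5, 29.0, 35.0,
    ),
    background_concentration: float = 0.01258,
    threshold_fraction: float = _iso.DEFAULT_THRESHOLD,
    acquisition_time_min: float = 30.0,
    noise_scale: float = _ph.DEFAULT_NOISE_SCALE,
    psf_fwhm_mm: float = _ph.DEFAULT_PSF_FWHM_MM,
    seed: int = 0,
) -> tuple[RCSurface, list[RCSample]]:
    """Calibrate an RC surface on the simulated six-sphere phantom.

    One simulation per gold-standard contrast level (all six spheres share
    the level), long acquisition time to keep calibration noise low.
    Samples whose measured L/B_m falls outside the surface validity box
    ``LBM_RANGE`` are discarded (a contour in the lesion-barely-hotter-than-
    background regime balloons into the background and carries no usable
    recovery information).  Remaining samples are grouped per sphere, each
    group fitted with the hyperbola, and the curve labelled by the sphere's
    mean measured isocontour diameter.
    """
    per_sphere: dict[float, list[RCSample]] = {
        d: [] for d in _ph.SIX_SPHERE_DIAMETERS_MM
    }
    for li, lb_gs in enumerate(lb_gs_levels):
        spec = _ph.six_sphere_phantom(
            sphere_concentrations=lb_gs * background_concentration,
            background_concentration=background_concentration,
            psf_fwhm_mm=psf_fwhm_mm,
            acquisition_time_min=acquisition_time_min,
            noise_scale=noise_scale,
            seed=seed * 10007 + li,
        )
        # re-seat the sphere holder each session: sub-voxel placement phases
        # vary between measurements exactly as lesion positions do in patients
        rng = np.random.default_rng(spec.seed + 1)
        for lesion in spec.lesions:
            jitter = (rng.random(3) - 0.5) * np.asarray(spec.voxel_size_mm)
            lesion.center_mm = tuple(
                c + off for c, off in zip(lesion.center_mm, jitter)
            )
        vol = _ph.simulate_phantom(spec)
        for lesion in spec.lesions:
            seed_vox = np.rint(
                np.asarray(lesion.center_mm) / np.asarray(spec.voxel_size_mm)
            ).astype(int)
            try:
                m = _iso.measure_at_threshold(
                    vol,
                    seed_vox,
                    threshold_fraction,
                    search_radius_mm=lesion.diameter_mm,
                )
            except ValueError:
                # ballooned low-contrast contour: no valid background ring;
                # the sample would fall outside the validity box anyway
                continue
            if LBM_RANGE[0] <= m.lbm <= LBM_RANGE[1]:
                per_sphere[lesion.diameter_mm].append(
                    RCSample(
                        d_actual_mm=lesion.diameter_mm,
                        d_measured_mm=m.d_thr_mm,
                        lbm=m.lbm,
                        lb_gs=lb_gs,
                    )
                )
    samples = [s for group in per_sphere.values() for s in group]
    curves = [fit_rc_curve(group) for group in per_sphere.values() if len(group) >= 4]
    surface = build_rc_surface(curves, threshold_fraction=threshold_fraction)
    return surface, samples
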