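"""Digital PET phantom simulator.

Builds noiseless activity maps for sphere-in-cylinder phantoms (and lumpy
"blob" lesions mimicking zeolite inserts), then emulates PET acquisition by
isotropic Gaussian blurring (the scanner point-spread function, the physical
origin of the partial volume effect: spill-out of lesion activity and
spill-in of background) plus signal-dependent Gaussian noise whose standard
deviation scales as 1/sqrt(acquisition time).

Array axis order is (slice, row, col); voxel sizes are stored per axis in the
same order, i.e. ``(dz, dy, dx)``.  Physical mm coordinates refer to voxel
centers, with voxel (0, 0, 0) at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "VolumeImage",
    "rasterize_phantom",
    "simulate_pet",
    "simulate_phantom",
    "six_sphere_phantom",
    "single_sphere_phantom",
    "DEFAULT_VOXEL_SIZE_MM",
    "DEFAULT_PSF_FWHM_MM",
    "DEFAULT_NOISE_SCALE",
]

#: (dz, dy, dx) of a clinical whole-body PET reconstruction grid.
DEFAULT_VOXEL_SIZE_MM = (3.27, 4.7, 4.7)
#: Isotropic reconstructed-image resolution assumed by default (intrinsic
#: 4-5 mm scanner class plus reconstruction smoothing).
DEFAULT_PSF_FWHM_MM = 7.0
#: Noise amplitude: std = noise_scale * sqrt(signal) / sqrt(t_min).
DEFAULT_NOISE_SCALE = 0.02

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Relative control points (offset in units of equivalent radius, radius in the
# same units) giving a lumpy, non-spherical union-of-spheres blob.
_DEFAULT_BLOB_CONTROL_POINTS = (
    ((0.0, 0.0, 0.0), 0.75),
    ((0.45, 0.35, 0.0), 0.55),
    ((-0.35, -0.15, 0.4), 0.6),
    ((0.1, -0.5, -0.35), 0.5),
)


@dataclass
class LesionSpec:
    """One simulated lesion: a sphere or a lumpy blob.

    ``diameter_mm`` is the actual diameter for spheres and the
    sphere-equivalent diameter (same volume) for blobs.  ``concentration`` is
    the gold-standard mean radioactivity concentration in MBq/mL;
    for ``uniformity="gradient"`` the voxel profile decreases from core to
    edge with the given peak-to-edge ratio while keeping that mean.
    """

    diameter_mm: float
    center_mm: tuple[float, float, float]
    concentration: float
    shape: str = "sphere"  # "sphere" | "blob"
    uniformity: str = "uniform"  # "uniform" | "gradient"
    peak_to_edge_ratio: float = 3.0
    control_points: Sequence[tuple[tuple[float, float, float], float]] | None = None

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("lesion diameter must be positive")
        if self.concentration < 0:
            raise ValueError("lesion concentration must be non-negative")
        if self.shape not in ("sphere", "blob"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")
        if self.uniformity not in ("uniform", "gradient"):
            raise ValueError(f"unknown uniformity {self.uniformity!r}")
        if self.uniformity == "gradient" and self.peak_to_edge_ratio <= 1:
            raise ValueError("peak_to_edge_ratio must exceed 1 for gradient uptake")


@dataclass
class PhantomSpec:
    """Declarative phantom description: elliptical-cylinder background plus lesions.

    The background is an elliptical cylinder with in-plane semi-axes
    ``background_semi_axes_mm = (ay, ax)`` and height ``background_height_mm``
    along the slice axis, centered at ``background_center_mm``.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM
    background_semi_axes_mm: tuple[float, float] = (120.0, 150.0)
    background_height_mm: float = 210.0
    background_center_mm: tuple[float, float, float] | None = None
    background_concentration: float = 0.01258
    lesions: list[LesionSpec] = field(default_factory=list)
    psf_fwhm_mm: float = DEFAULT_PSF_FWHM_MM
    acquisition_time_min: float = 2.5
    noise_scale: float = DEFAULT_NOISE_SCALE
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.background_concentration < 0:
            raise ValueError("background concentration must be non-negative")
        if self.psf_fwhm_mm <= 0:
            raise ValueError("psf_fwhm_mm must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.background_center_mm is None:
            self.background_center_mm = tuple(
                (n - 1) / 2.0 * v for n, v in zip(self.grid_shape, self.voxel_size_mm)
            )

    def contains(self, point_mm: Sequence[float]) -> bool:
        """True if a physical point lies inside the background cylinder."""
        cz, cy, cx = self.background_center_mm
        ay, ax = self.background_semi_axes_mm
        z, y, x = point_mm
        if abs(z - cz) > self.background_height_mm / 2.0:
            return False
        return ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0


@dataclass
class VolumeImage:
    """3-D concentration grid (MBq/mL) with voxel spacing and ground truth.

    ``ground_truth`` (for simulated volumes) holds per-lesion gold-standard
    concentration, sphere-equivalent diameter and center, plus the background
    concentration — the digital analogue of dose-calibrator records.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("VolumeImage requires a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_to_mm(self, index: Sequence[float]) -> np.ndarray:
        return np.asarray(index, dtype=float) * np.asarray(self.voxel_size_mm)

    def mm_to_voxel(self, point_mm: Sequence[float]) -> np.ndarray:
        return np.asarray(point_mm, dtype=float) / np.asarray(self.voxel_size_mm)

    # ---- I/O ------------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        """Write NIfTI (axes reordered to x, y, z) plus a YAML ground-truth sidecar."""
        import nibabel as nib

        path = Path(path)
        dz, dy, dx = self.voxel_size_mm
        affine = np.diag([dx, dy, dz, 1.0])
        img = nib.Nifti1Image(np.transpose(self.values, (2, 1, 0)), affine)
        nib.save(img, str(path))
        if self.ground_truth is not None:
            sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
            with open(str(sidecar) + ".truth.yaml", "w") as fh:
                yaml.safe_dump(_plain(self.ground_truth), fh, sort_keys=False)

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VolumeImage":
        import nibabel as nib

        path = Path(path)
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
        values = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 1, 0))
        truth = None
        sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".truth.yaml")
        if sidecar.exists():
            with open(sidecar) as fh:
                truth = yaml.safe_load(fh)
        return cls(values, (float(zooms[2]), float(zooms[1]), float(zooms[0])), truth)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Rasterization


def _coordinate_axes(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(
        np.arange(n) * v for n, v in zip(spec.grid_shape, spec.voxel_size_mm)
    )


def _sphere_occupancy(
    spec: PhantomSpec, center: np.ndarray, radius: float
) -> np.ndarray:
    """Per-voxel occupancy fraction of a sphere, 3x3x3 supersampled at the shell."""
    z, y, x = _coordinate_axes(spec)
    dist = np.sqrt(
        (z[:, None, None] - center[0]) ** 2
        + (y[None, :, None] - center[1]) ** 2
        + (x[None, None, :] - center[2]) ** 2
    )
    half_diag = 0.5 * np.linalg.norm(spec.voxel_size_mm)
    occ = (dist <= radius - half_diag).astype(float)
    shell = (dist > radius - half_diag) & (dist < radius + half_diag)
    if np.any(shell):
        n_sub = 5  # 5^3 midpoint rule keeps volume error ~1% down to 10 mm spheres
        offsets = (np.arange(n_sub) - (n_sub - 1) / 2.0) / n_sub
        sz, sy, sx = np.meshgrid(
            offsets * spec.voxel_size_mm[0],
            offsets * spec.voxel_size_mm[1],
            offsets * spec.voxel_size_mm[2],
            indexing="ij",
        )
        sub = np.stack([sz.ravel(), sy.ravel(), sx.ravel()], axis=1)  # (n^3, 3)
        idx = np.argwhere(shell)
        centers = idx * np.asarray(spec.voxel_size_mm)
        pts = centers[:, None, :] + sub[None, :, :]
        inside = np.linalg.norm(pts - center, axis=2) <= radius
        occ[shell] = inside.mean(axis=1)
    return occ


from functools import lru_cache


@lru_cache(maxsize=32)
def _blob_unit_volume(control_points) -> float:
    """Volume of the unit-scale union of sub-spheres (fine-grid estimate)."""
    pts = np.array([p for p, _ in control_points])
    radii = np.array([r for _, r in control_points])
    lo = (pts - radii[:, None]).min(axis=0)
    hi = (pts + radii[:, None]).max(axis=0)
    step = 0.02
    axes = [np.arange(l, h + step, step) for l, h in zip(lo, hi)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    inside = np.zeros(zz.shape, dtype=bool)
    for (pz, py, px), r in zip(pts, radii):
        inside |= (zz - pz) ** 2 + (yy - py) ** 2 + (xx - px) ** 2 <= r**2
    return float(inside.sum()) * step**3


def _blob_occupancy(spec: PhantomSpec, lesion: LesionSpec) -> np.ndarray:
    cps = tuple(
        (tuple(p), float(r))
        for p, r in (lesion.control_points or _DEFAULT_BLOB_CONTROL_POINTS)
    )
    r_eq = lesion.diameter_mm / 2.0
    target_volume = 4.0 / 3.0 * np.pi * r_eq**3
    # Uniform scale so the union volume matches the sphere-equivalent volume.
    scale = r_eq * (target_volume / (_blob_unit_volume(cps) * r_eq**3)) ** (1.0 / 3.0)
    occ = np.zeros(spec.grid_shape)
    center = np.asarray(lesion.center_mm, dtype=float)
    for offset, radius in cps:
        sub_center = center + scale * np.asarray(offset)
        occ = np.maximum(occ, _sphere_occupancy(spec, sub_center, scale * radius))
    return np.clip(occ, 0.0, 1.0)


def _lesion_profile(spec: PhantomSpec, lesion: LesionSpec, occ: np.ndarray) -> np.ndarray:
    """Voxel concentrations inside the lesion footprint (mean == GS concentration)."""
    if lesion.uniformity == "uniform":
        return np.full_like(occ, lesion.concentration)
    mask = occ > 0.5
    if not np.any(mask):
        return np.full_like(occ, lesion.concentration)
    depth = ndimage.distance_transform_edt(mask, sampling=spec.voxel_size_mm)
    dmax = depth.max()
    rel = depth / dmax if dmax > 0 else np.zeros_like(depth)
    k = lesion.peak_to_edge_ratio
    shape = 1.0 + (k - 1.0) * rel  # edge=1, core=k
    w = occ * shape
    mean_shape = float((w.sum()) / occ.sum())
    return lesion.concentration * shape / mean_shape


def rasterize_phantom(spec: PhantomSpec) -> VolumeImage:
    """Render a noiseless, unblurred activity map from a phantom description.

    Boundary voxels of each lesion are weighted by their sub-voxel occupancy
    fraction (3x3x3 supersampling), so the total activity of a lesion matches
    concentration x volume to well under the measurement tolerances.
    """
    z, y, x = _coordinate_axes(spec)
    cz, cy, cx = spec.background_center_mm
    ay, ax = spec.background_semi_axes_mm
    in_cyl = (
        (((y[None, :, None] - cy) / ay) ** 2 + ((x[None, None, :] - cx) / ax) ** 2)
        <= 1.0
    ) & (np.abs(z[:, None, None] - cz) <= spec.background_height_mm / 2.0)
    vol = np.where(in_cyl, spec.background_concentration, 0.0)

    truth_lesions = []
    for i, lesion in enumerate(spec.lesions):
        if not spec.contains(lesion.center_mm):
            raise ValueError(
                f"lesion {i} (d={lesion.diameter_mm} mm) center {lesion.center_mm} "
                "lies outside the background region"
            )
        if lesion.shape == "sphere":
            occ = _sphere_occupancy(
                spec, np.asarray(lesion.center_mm, float), lesion.diameter_mm / 2.0
            )
        else:
            occ = _blob_occupancy(spec, lesion)
        profile = _lesion_profile(spec, lesion, occ)
        vol = vol * (1.0 - occ) + profile * occ
        truth_lesions.append(
            {
                "id": i,
                "shape": lesion.shape,
                "uniformity": lesion.uniformity,
                "diameter_mm": float(lesion.diameter_mm),
                "center_mm": [float(c) for c in lesion.center_mm],
                "concentration": float(lesion.concentration),
            }
        )

    truth = {
        "background_concentration": float(spec.background_concentration),
        "lesions": truth_lesions,
    }
    return VolumeImage(vol, spec.voxel_size_mm, truth)


# ---------------------------------------------------------------------------
# PET acquisition emulation


def simulate_pet(
    activity: VolumeImage,
    psf_fwhm_mm: float = DEFAULT_PSF_FWHM_MM,
    acquisition_time_min: float = 2.5,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    seed: int = 0,
) -> VolumeImage:
    """Blur an activity map with an isotropic Gaussian PSF and add noise.

    The additive noise is zero-mean Gaussian with standard deviation
    ``noise_scale * sqrt(blurred value) / sqrt(acquisition_time_min)``
    (reconstructed-image noise scaling with counts), and the result is
    clipped at zero.  ``noise_scale=0`` yields the pure convolution, which
    conserves total activity up to boundary truncation.
    """
    if psf_fwhm_mm <= 0:
        raise ValueError("psf_fwhm_mm must be positive")
    if acquisition_time_min <= 0:
        raise ValueError("acquisition_time_min must be positive")
    sigma_vox = [
        psf_fwhm_mm * _FWHM_TO_SIGMA / v for v in activity.voxel_size_mm
    ]
    blurred = ndimage.gaussian_filter(activity.values, sigma=sigma_vox, mode="constant")
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        std = noise_scale * np.sqrt(np.maximum(blurred, 0.0)) / np.sqrt(
            acquisition_time_min
        )
        blurred = blurred + rng.normal(0.0, 1.0, blurred.shape) * std
    return VolumeImage(
        np.clip(blurred, 0.0, None), activity.voxel_size_mm, activity.ground_truth
    )


def simulate_phantom(spec: PhantomSpec) -> VolumeImage:
    """rasterize_phantom + simulate_pet with the spec's acquisition settings."""
    return simulate_pet(
        rasterize_phantom(spec),
        psf_fwhm_mm=spec.psf_fwhm_mm,
        acquisition_time_min=spec.acquisition_time_min,
        noise_scale=spec.noise_scale,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# Canned geometries

SIX_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 23.0, 29.0, 37.0)


def six_sphere_phantom(
    sphere_concentrations: Sequence[float] | float,
    background_concentration: float = 0.01258,
    diameters_mm: Sequence[float] = SIX_SPHERE_DIAMETERS_MM,
    ring_radius_mm: float = 80.0,
    **acquisition,
) -> PhantomSpec:
    """Six hot spheres on a ring inside the elliptical calibration cylinder.

    Mirrors the standard RC calibration setup: an elliptical cylinder
    (24 x 30 cm section, 21 cm height) of warm background with six spheres of
    10-37 mm diameter.  ``sphere_concentrations`` may be a scalar (same for
    all spheres) or one value per sphere.
    """
    if np.isscalar(sphere_concentrations):
        sphere_concentrations = [float(sphere_concentrations)] * len(diameters_mm)
    if len(sphere_concentrations) != len(diameters_mm):
        raise ValueError("need one concentration per sphere")
    grid_shape = (66, 56, 70)
    spec = PhantomSpec(
        grid_shape=grid_shape,
        background_concentration=background_concentration,
        **acquisition,
    )
    cz, cy, cx = spec.background_center_mm
    # spheres sit on a common axial plane through a slice center, as when the
    # sphere holder is aligned with the scanner's slice grid
    cz = round(cz / spec.voxel_size_mm[0]) * spec.voxel_size_mm[0]
    angles = np.linspace(0.0, 2.0 * np.pi, len(diameters_mm), endpoint=False)
    for d, conc, ang in zip(diameters_mm, sphere_concentrations, angles):
        spec.lesions.append(
            LesionSpec(
                diameter_mm=d,
                center_mm=(
                    cz,
                    cy + ring_radius_mm * np.sin(ang) * 0.9,
                    cx + ring_radius_mm * np.cos(ang),
                ),
                concentration=conc,
            )
        )
    return spec


def single_sphere_phantom(
    diameter_mm: float,
    sphere_concentration: float,
    background_concentration: float = 0.01258,
    **acquisition,
) -> PhantomSpec:
    """One centered sphere in a compact warm cylinder (fast unit of simulation)."""
    spec = PhantomSpec(
        grid_shape=(31, 26, 26),
        background_semi_axes_mm=(58.0, 58.0),
        background_height_mm=96.0,
        background_concentration=background_concentration,
        **acquisition,
    )
    spec.lesions.append(
        LesionSpec(
            diameter_mm=diameter_mm,
            center_mm=spec.background_center_mm,
            concentration=sphere_concentration,
        )
    )
    return spec
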