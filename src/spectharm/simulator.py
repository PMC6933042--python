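"""Synthetic reconstructed-image simulator for quantitative SPECT.

Stands in for scanner acquisitions: the reconstructed image domain is
emulated directly as the true activity map blurred by a system-dependent
isotropic Gaussian point-spread function (partial-volume loss), scaled to
expected counts through the system calibration factor and the acquisition
duty (projections x time per projection x voxel volume), and optionally
degraded by independent per-voxel Poisson count noise.  No projection-space
or tomographic-reconstruction modeling is attempted.

The effective resolution per system is the quadrature sum of the SPECT
resolution and any post-reconstruction Gaussian filter.  Enlarged-phantom
(high-BMI) acquisitions may additionally be degraded by a count-scaling
factor < 1 (attenuation) and an additive FWHM term (increased
source-detector distance); these are tunable profile values, not measured
quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from pydantic import BaseModel, Field
from scipy.ndimage import gaussian_filter

from .phantom_geometry import ActivityMap, _as_voxel_vector

__all__ = [
    "UNIT_COUNTS",
    "UNIT_KBQ_PER_ML",
    "SizeDegradation",
    "SystemProfile",
    "AcquisitionSettings",
    "QuantImage",
    "simulate_recon",
    "simulate_replicates",
    "resample_activity",
]

UNIT_COUNTS = "counts"
UNIT_KBQ_PER_ML = "kBq/ml"

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class SizeDegradation(BaseModel):
    """Extra image degradation for enlarged (high-BMI) phantom acquisitions."""

    count_scale: float = Field(gt=0, le=1.0, default=1.0)
    fwhm_add_mm: float = Field(ge=0, default=0.0)


DEFAULT_SIZE_DEGRADATION: dict[str, SizeDegradation] = {
    "small": SizeDegradation(count_scale=1.0, fwhm_add_mm=0.0),
    "medium": SizeDegradation(count_scale=0.6, fwhm_add_mm=1.0),
    "large": SizeDegradation(count_scale=0.25, fwhm_add_mm=2.0),
}


class SystemProfile(BaseModel):
    """Per-scanner imaging characteristics and calibration.

    ``calibration_factor`` converts activity concentration to count rate
    density, in (cps/ml)/(kBq/ml).  ``calibration_bias`` is a unitless
    multiplicative cross-calibration error applied at simulation time only;
    a perfectly cross-calibrated system has bias 1.0.
    """

    name: str
    psf_fwhm_mm: float = Field(gt=0)
    post_filter_fwhm_mm: float = Field(ge=0, default=0.0)
    sensitivity_cps_per_mbq: float = Field(gt=0)
    voxel_size_mm: tuple[float, float, float]
    n_projections: int = Field(ge=1, default=128)
    calibration_factor: float = Field(gt=0)
    calibration_bias: float = Field(gt=0, default=1.0)
    size_degradation: dict[str, SizeDegradation] = Field(
        default_factory=lambda: {k: v.model_copy() for k, v in DEFAULT_SIZE_DEGRADATION.items()}
    )

    def effective_fwhm_mm(self, size_class: str = "small") -> float:
        """System + reconstruction-filter FWHM (quadrature) plus any size term."""
        base = math.hypot(self.psf_fwhm_mm, self.post_filter_fwhm_mm)
        deg = self.size_degradation.get(size_class)
        return base + (deg.fwhm_add_mm if deg is not None else 0.0)

    def count_scale(self, size_class: str = "small") -> float:
        deg = self.size_degradation.get(size_class)
        return deg.count_scale if deg is not None else 1.0


class AcquisitionSettings(BaseModel):
    """Acquisition duty cycle and the RNG seed of a noisy realization."""

    n_projections: int = Field(ge=1)
    time_per_projection_s: float = Field(gt=0)
    seed: int | None = None


@dataclass
class QuantImage:
    """A 3D voxel image with a unit tag and acquisition provenance.

    ``grid`` is indexed (x, y, z); ``unit`` is either counts or kBq/ml.
    """

    grid: np.ndarray
    voxel_size_mm: np.ndarray
    origin_mm: np.ndarray
    unit: str
    settings: AcquisitionSettings
    profile_name: str = ""

    def __post_init__(self) -> None:
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) * 1e-3

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin_mm[i] + np.arange(self.grid.shape[i]) * self.voxel_size_mm[i]
            for i in range(3)
        )


def resample_activity(truth: ActivityMap, voxel_size_mm) -> ActivityMap:
    """Linearly resample an activity map onto a new voxel size, keeping the
    physical field of view (and its center) fixed.  No-op when sizes match."""
    new_h = _as_voxel_vector(voxel_size_mm)
    if np.allclose(truth.voxel_size_mm, new_h, rtol=0, atol=1e-9):
        return truth
    old_h = truth.voxel_size_mm
    old_n = np.asarray(truth.grid.shape)
    center = truth.origin_mm + (old_n - 1) / 2.0 * old_h
    new_n = np.maximum(np.ceil(old_n * old_h / new_h).astype(int), 1)
    new_origin = center - (new_n - 1) / 2.0 * new_h

    img = sitk.GetImageFromArray(np.ascontiguousarray(truth.grid.transpose(2, 1, 0)))
    img.SetSpacing(tuple(old_h))
    img.SetOrigin(tuple(truth.origin_mm))
    out = sitk.Resample(
        img,
        size=[int(v) for v in new_n],
        transform=sitk.Transform(),
        interpolator=sitk.sitkLinear,
        outputOrigin=tuple(new_origin),
        outputSpacing=tuple(new_h),
        outputDirection=img.GetDirection(),
        defaultPixelValue=0.0,
    )
    grid = sitk.GetArrayFromImage(out).transpose(2, 1, 0).astype(float)
    np.maximum(grid, 0.0, out=grid)
    return ActivityMap(grid=grid, voxel_size_mm=new_h, origin_mm=new_origin)


def simulate_recon(
    truth: ActivityMap,
    profile: SystemProfile,
    settings: AcquisitionSettings,
    *,
    noiseless: bool = False,
    size_class: str = "small",
) -> QuantImage:
    """Emulate a reconstructed SPECT image (in counts) of a true activity map.

    Expected counts per voxel are
    ``(truth * Gaussian(FWHM)) * CF * bias * t * n * voxel_volume * count_scale``.
    With ``noiseless`` the expectation is returned; otherwise every voxel is
    an independent Poisson draw with that mean, using ``settings.seed``.
    """
    truth = resample_activity(truth, profile.voxel_size_mm)
    h = truth.voxel_size_mm
    fwhm = profile.effective_fwhm_mm(size_class)
    sigma_vox = (fwhm * _FWHM_TO_SIGMA) / h
    if np.any(sigma_vox > 1e-6):
        blurred = gaussian_filter(truth.grid, sigma=tuple(sigma_vox), mode="constant", cval=0.0)
    else:
        blurred = truth.grid.copy()
    nu_ml = truth.voxel_volume_ml
    scale = (
        profile.calibration_factor
        * profile.calibration_bias
        * settings.time_per_projection_s
        * settings.n_projections
        * nu_ml
        * profile.count_scale(size_class)
    )
    expected = blurred * scale
    np.maximum(expected, 0.0, out=expected)  # clip convolution round-off dust
    if noiseless:
        grid = expected
    else:
        if settings.seed is None:
            raise ValueError("a seed is required for a noisy realization")
        rng = np.random.default_rng(settings.seed)
        grid = rng.poisson(expected).astype(float)
    return QuantImage(
        grid=grid,
        voxel_size_mm=h,
        origin_mm=truth.origin_mm,
        unit=UNIT_COUNTS,
        settings=settings.model_copy(),
        profile_name=profile.name,
    )


def simulate_replicates(
    truth: ActivityMap,
    profile: SystemProfile,
    settings: AcquisitionSettings,
    n_replicates: int,
    base_seed: int,
    *,
    noiseless: bool = False,
    size_class: str = "small",
) -> list[QuantImage]:
    """``n_replicates`` independent realizations with per-replicate seeds
    derived deterministically as ``base_seed + replicate_index``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = []
    for i in range(n_replicates):
        s = settings.model_copy(update={"seed": int(base_seed) + i})
        out.append(
            simulate_recon(truth, profile, s, noiseless=noiseless, size_class=size_class)
        )
    return out
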