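"""The quantification chain: calibration factor, background VOIs,
threshold-based region-growing sphere segmentation, recovery coefficients.

The calibration factor converts reconstructed counts to activity
concentration,

    CF [(cps/ml)/(kBq/ml)] = (mu / (t * n * nu)) / A

with mu the mean voxel value in a uniform region, t the time per
projection, n the number of projections, nu the voxel volume in ml and A
the true concentration.  Sphere VOIs are grown from the hottest voxel near
the known sphere center down to the background-corrected half-maximum
threshold

    VV_thresh = 0.5 * (VV_max,sphere + VV_mean,bg)

and the recovery coefficient of a sphere is RC = a / A, the imaged over the
true activity concentration, evaluated for both the mean and the maximum
voxel value of the VOI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom_geometry import PhantomSpec, SphereSpec
from .simulator import QuantImage, UNIT_COUNTS, UNIT_KBQ_PER_ML

__all__ = [
    "NoContrastError",
    "PlacementError",
    "VOIMask",
    "CalibrationResult",
    "RCRecord",
    "compute_cf",
    "counts_to_concentration",
    "place_background_vois",
    "cylinder_roi",
    "segment_sphere",
    "compute_rc",
    "compute_background_rc",
]


class NoContrastError(RuntimeError):
    """Sphere segmentation failed: no voxel in the search region exceeds the
    background mean (the low-contrast failure mode of the smallest sphere)."""


class PlacementError(RuntimeError):
    """Background VOIs cannot be placed without violating margins."""


@dataclass
class VOIMask:
    """A set of voxel indices with provenance.

    ``indices`` is an (N, 3) integer array into an (x, y, z)-indexed grid.
    """

    indices: np.ndarray
    kind: str  # "sphere" | "background_cylinder"
    label: str
    threshold_used: float | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.indices.shape[0])

    def values(self, image: QuantImage) -> np.ndarray:
        i = self.indices
        return image.grid[i[:, 0], i[:, 1], i[:, 2]]

    def volume_ml(self, image: QuantImage) -> float:
        return self.n_voxels * image.voxel_volume_ml

    def to_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        i = self.indices
        m[i[:, 0], i[:, 1], i[:, 2]] = True
        return m


@dataclass
class CalibrationResult:
    """A calibration-factor determination from a uniform acquisition."""

    cf: float
    mean_voxel_value: float
    time_per_projection_s: float
    n_projections: int
    voxel_volume_ml: float
    true_concentration_kbq_per_ml: float

    @classmethod
    def from_factor(
        cls, cf: float, time_per_projection_s: float, n_projections: int, voxel_volume_ml: float
    ) -> "CalibrationResult":
        """Wrap an externally known CF (e.g. a system profile value) so it can
        be applied to images; the identity mu = cf*A*t*n*nu is kept with A=1."""
        if cf <= 0:
            raise ValueError("calibration factor must be positive")
        return cls(
            cf=cf,
            mean_voxel_value=cf * time_per_projection_s * n_projections * voxel_volume_ml,
            time_per_projection_s=time_per_projection_s,
            n_projections=n_projections,
            voxel_volume_ml=voxel_volume_ml,
            true_concentration_kbq_per_ml=1.0,
        )


@dataclass
class RCRecord:
    """Recovery coefficients of one sphere in one replicate on one system."""

    sphere_diameter_mm: float
    rc_mean: float
    rc_max: float
    voi_volume_ml: float
    system: str = ""
    phantom: str = ""
    replicate: int = 0


def compute_cf(
    uniform_image: QuantImage, roi: VOIMask, true_concentration_kbq_per_ml: float
) -> CalibrationResult:
    """Calibration factor from a uniform-region acquisition in counts."""
    if uniform_image.unit != UNIT_COUNTS:
        raise ValueError("calibration requires an image in counts")
    if true_concentration_kbq_per_ml <= 0:
        raise ValueError("true concentration must be positive")
    if roi.n_voxels == 0:
        raise ValueError("calibration ROI is empty")
    mu = float(np.mean(roi.values(uniform_image)))
    t = uniform_image.settings.time_per_projection_s
    n = uniform_image.settings.n_projections
    nu = uniform_image.voxel_volume_ml
    cf = (mu / (t * n * nu)) / true_concentration_kbq_per_ml
    return CalibrationResult(
        cf=cf,
        mean_voxel_value=mu,
        time_per_projection_s=t,
        n_projections=n,
        voxel_volume_ml=nu,
        true_concentration_kbq_per_ml=true_concentration_kbq_per_ml,
    )


def counts_to_concentration(image: QuantImage, cal: CalibrationResult) -> QuantImage:
    """Convert a counts image to activity concentration (kBq/ml) by the
    inverse calibration relation: each voxel divided by cf*t*n*nu."""
    if image.unit != UNIT_COUNTS:
        raise ValueError("expected an image in counts")
    if cal.cf <= 0:
        raise ValueError("calibration factor must be positive")
    t = image.settings.time_per_projection_s
    n = image.settings.n_projections
    nu = image.voxel_volume_ml
    return QuantImage(
        grid=image.grid / (cal.cf * t * n * nu),
        voxel_size_mm=image.voxel_size_mm.copy(),
        origin_mm=image.origin_mm.copy(),
        unit=UNIT_KBQ_PER_ML,
        settings=image.settings.model_copy(),
        profile_name=image.profile_name,
    )


def _indices_in_predicate(image: QuantImage, predicate) -> np.ndarray:
    x, y, z = image.axis_coords()
    m = predicate(x[:, None, None], y[None, :, None], z[None, None, :])
    return np.argwhere(m)


def cylinder_roi(
    image: QuantImage,
    center_mm: tuple[float, float, float],
    radius_mm: float,
    height_mm: float,
    label: str = "roi",
) -> VOIMask:
    """Axial cylinder VOI: voxel centers within ``radius_mm`` of the axis
    through ``center_mm`` and within ``height_mm/2`` axially."""
    cx, cy, cz = center_mm
    idx = _indices_in_predicate(
        image,
        lambda x, y, z: ((x - cx) ** 2 + (y - cy) ** 2 <= radius_mm**2)
        & (np.abs(z - cz) <= height_mm / 2.0),
    )
    if idx.shape[0] == 0:
        raise PlacementError(f"cylinder ROI {label!r} contains no voxels")
    return VOIMask(indices=idx, kind="background_cylinder", label=label)


def place_background_vois(
    image: QuantImage,
    spec: PhantomSpec,
    n_cylinders: int = 6,
    diameter_cm: float = 4.5,
    height_cm: float = 4.0,
    sphere_margin_mm: float = 15.0,
    wall_margin_mm: float = 10.0,
    ring_radius_mm: float = 45.0,
) -> tuple[list[VOIMask], float]:
    """Place cylindrical background VOIs in the uniform compartment.

    Cylinders sit on a ring about the phantom axis, in two groups offset
    axially on either side of the sphere plane so that every cylinder keeps
    ``sphere_margin_mm`` clearance from every sphere surface and
    ``wall_margin_mm`` from the phantom wall.  Returns the masks and the
    pooled (unweighted, all voxels of all cylinders) background mean.
    """
    r_cyl = diameter_cm * 10.0 / 2.0
    h_cyl = height_cm * 10.0
    body = spec.body

    if ring_radius_mm + r_cyl + wall_margin_mm > body.cap_radius_mm:
        raise PlacementError("cylinders do not fit radially inside the body outline")
    sphere_top = max((abs(s.center_mm[2]) + s.radius_mm) for s in spec.spheres) if spec.spheres else 0.0
    zc = sphere_top + sphere_margin_mm + h_cyl / 2.0
    if zc + h_cyl / 2.0 + wall_margin_mm > body.length_mm / 2.0:
        raise PlacementError("cylinders do not fit axially between spheres and end wall")
    if n_cylinders >= 2:
        per_side = math.ceil(n_cylinders / 2)
        min_sep = 2.0 * ring_radius_mm * math.sin(math.pi / per_side) if per_side > 1 else np.inf
        if min_sep < 2.0 * r_cyl:
            raise PlacementError("cylinders on the ring would overlap")

    masks: list[VOIMask] = []
    for i in range(n_cylinders):
        side = 1.0 if i % 2 == 0 else -1.0
        k = i // 2
        per_side = math.ceil(n_cylinders / 2) if side > 0 else n_cylinders // 2
        ang = math.radians(30.0 + (0.0 if side > 0 else 60.0) + k * 360.0 / max(per_side, 1))
        center = (
            ring_radius_mm * math.cos(ang),
            ring_radius_mm * math.sin(ang),
            side * zc,
        )
        masks.append(
            cylinder_roi(image, center, r_cyl, h_cyl, label=f"bg_cyl_{i}")
        )
    pooled = np.concatenate([m.values(image) for m in masks])
    return masks, float(np.mean(pooled))


def segment_sphere(
    image: QuantImage,
    sphere: SphereSpec,
    vv_mean_bg: float,
    search_radius_mm: float | None = None,
) -> VOIMask:
    """Region-growing sphere segmentation with a background-corrected
    half-maximum threshold.

    The maximum voxel value is taken over a search ball around the nominal
    sphere center (default radius: sphere radius plus one voxel); the mask
    is the 26-connected component of ``value >= VV_thresh`` containing that
    maximum voxel.  Ties at the maximum break to the lowest linear index.
    """
    if search_radius_mm is None:
        search_radius_mm = sphere.radius_mm + float(np.max(image.voxel_size_mm))
    cx, cy, cz = sphere.center_mm
    x, y, z = image.axis_coords()
    lo_ok = all(
        c - search_radius_mm >= ax[0] - 0.5 * h and c + search_radius_mm <= ax[-1] + 0.5 * h
        for c, ax, h in zip((cx, cy, cz), (x, y, z), image.voxel_size_mm)
    )
    if not lo_ok:
        raise ValueError("search region extends outside the image bounds")

    ball = _indices_in_predicate(
        image,
        lambda X, Y, Z: (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= search_radius_mm**2,
    )
    if ball.shape[0] == 0:
        raise ValueError("empty search region")
    vals = image.grid[ball[:, 0], ball[:, 1], ball[:, 2]]
    imax = int(np.argmax(vals))  # first occurrence = lowest linear index
    vv_max = float(vals[imax])
    if vv_max <= vv_mean_bg:
        raise NoContrastError(
            f"no contrast for sphere {sphere.label!r}: max {vv_max:.4g} <= background {vv_mean_bg:.4g}"
        )
    threshold = 0.5 * (vv_max + vv_mean_bg)
    seed_idx = tuple(ball[imax])

    binary = image.grid >= threshold
    labels, _ = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    comp = labels[seed_idx]
    idx = np.argwhere(labels == comp)
    return VOIMask(indices=idx, kind="sphere", label=sphere.label, threshold_used=threshold)


def compute_rc(
    mask: VOIMask,
    image: QuantImage,
    true_concentration_kbq_per_ml: float,
    *,
    sphere_diameter_mm: float = float("nan"),
    system: str = "",
    phantom: str = "",
    replicate: int = 0,
) -> RCRecord:
    """Recovery coefficients RC = a/A for the mean and maximum VOI value."""
    if image.unit != UNIT_KBQ_PER_ML:
        raise ValueError("recovery coefficients require a concentration image (kBq/ml)")
    if true_concentration_kbq_per_ml <= 0:
        raise ValueError("true concentration must be positive")
    if mask.n_voxels == 0:
        raise ValueError("empty VOI")
    vals = mask.values(image)
    return RCRecord(
        sphere_diameter_mm=sphere_diameter_mm,
        rc_mean=float(np.mean(vals)) / true_concentration_kbq_per_ml,
        rc_max=float(np.max(vals)) / true_concentration_kbq_per_ml,
        voi_volume_ml=mask.volume_ml(image),
        system=system,
        phantom=phantom,
        replicate=replicate,
    )


def compute_background_rc(
    image: QuantImage,
    background_vois: list[VOIMask],
    true_background_kbq_per_ml: float,
) -> float:
    """Pooled background recovery: mean over all background-VOI voxels / A."""
    if image.unit != UNIT_KBQ_PER_ML:
        raise ValueError("background recovery requires a concentration image (kBq/ml)")
    if true_background_kbq_per_ml <= 0:
        raise ValueError("true background concentration must be positive")
    pooled = np.concatenate([m.values(image) for m in background_vois])
    return float(np.mean(pooled)) / true_background_kbq_per_ml
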