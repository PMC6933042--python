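"""Fillable body-phantom geometry and partial-volume-accurate rasterization.

The NEMA IEC body phantom is a torso-shaped fillable shell — two lateral
semicircles joined by straight top/bottom wall segments, extruded axially —
holding six hollow spheres (inner diameters 10–37 mm) on a transaxial ring.
Filled with a radiotracer solution at a known sphere-to-background
concentration ratio it is the standard object for recovery-coefficient and
image-quality tests in emission tomography.

This module describes such phantoms (including enlarged variants that
emulate obese patients) and rasterizes them onto voxel grids as
activity-concentration maps.  Voxels that straddle a material interface are
resolved by regular sub-voxel sampling so that they carry volume-weighted
concentrations; interior voxels are classified analytically and carry the
exact compartment concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "GeometryError",
    "SphereSpec",
    "BodyOutline",
    "PhantomSpec",
    "ActivityMap",
    "nominal_sphere_volume",
    "build_standard_phantoms",
    "voxelize",
    "grid_axis_coords",
]

#: Radius (mm) of the transaxial ring on which the six sphere centers sit.
SPHERE_RING_RADIUS_MM = 57.2

#: Inner diameters (mm) of the six NEMA IEC spheres, largest first.
NEMA_SPHERE_DIAMETERS_MM = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)

#: Interior cross-section of the standard (small) torso shell, mm.
NEMA_BODY_WIDTH_MM = 300.0
NEMA_BODY_HEIGHT_MM = 230.0

DEFAULT_SPHERE_KBQ_PER_ML = 100.0
DEFAULT_BACKGROUND_KBQ_PER_ML = 10.0


class GeometryError(ValueError):
    """A phantom geometry constraint is violated (e.g. sphere outside body)."""


def nominal_sphere_volume(diameter_mm: float) -> float:
    """Nominal volume (ml) of a sphere with the given inner diameter (mm).

    Computed as (pi/6)*d^3 with d in cm.  For the six standard sphere
    diameters this reproduces the conventional printed volumes
    (0.5, 1.2, 2.6, 5.6, 11.5 and 26.5 ml) to one decimal.
    """
    if not diameter_mm > 0:
        raise ValueError(f"sphere diameter must be positive, got {diameter_mm}")
    return math.pi / 6.0 * (diameter_mm / 10.0) ** 3


class SphereSpec(BaseModel):
    """A fillable hollow sphere: label, inner diameter, position, fill concentration."""

    label: str
    inner_diameter_mm: float = Field(gt=0)
    center_mm: tuple[float, float, float]
    activity_kbq_per_ml: float = Field(ge=0)

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.inner_diameter_mm

    @property
    def nominal_volume_ml(self) -> float:
        return nominal_sphere_volume(self.inner_diameter_mm)


class BodyOutline(BaseModel):
    """Torso-shaped interior: a 2D 'stadium' cross-section extruded axially.

    The cross-section consists of two lateral semicircles of radius
    ``height/2`` joined by straight top and bottom segments of length
    ``width - height``; equivalently the set of points within ``height/2``
    of the central segment.  Coordinates are millimetres, origin at the
    phantom centroid, x lateral, y anterior-posterior, z axial.
    """

    width_mm: float = Field(gt=0)
    height_mm: float = Field(gt=0)
    length_mm: float = Field(gt=0)

    @model_validator(mode="after")
    def _check_aspect(self) -> "BodyOutline":
        if self.width_mm < self.height_mm:
            raise ValueError("body outline requires width >= height")
        return self

    @property
    def half_straight_mm(self) -> float:
        return 0.5 * (self.width_mm - self.height_mm)

    @property
    def cap_radius_mm(self) -> float:
        return 0.5 * self.height_mm

    @property
    def cross_section_area_mm2(self) -> float:
        return math.pi * self.cap_radius_mm**2 + 2.0 * self.half_straight_mm * self.height_mm

    @property
    def perimeter_mm(self) -> float:
        return 2.0 * math.pi * self.cap_radius_mm + 4.0 * self.half_straight_mm

    @property
    def volume_l(self) -> float:
        return self.cross_section_area_mm2 * self.length_mm * 1e-6

    def sdf2d(self, x, y):
        """Signed distance (mm) to the cross-section boundary; negative inside."""
        a = self.half_straight_mm
        qx = np.clip(x, -a, a)
        return np.hypot(x - qx, y) - self.cap_radius_mm

    def sdf(self, x, y, z):
        """Conservative signed distance to the 3D interior boundary.

        The max of the cross-section distance and the axial slab distance;
        exact inside and a lower bound on the true distance outside, which
        is sufficient for containment tests and interface detection.
        """
        return np.maximum(self.sdf2d(x, y), np.abs(z) - 0.5 * self.length_mm)


class PhantomSpec(BaseModel):
    """Geometric and activity description of a fillable body phantom."""

    name: str
    total_volume_l: float = Field(gt=0)
    waist_circumference_cm: float = Field(gt=0)
    bmi_kg_m2: float = Field(gt=0)
    background_kbq_per_ml: float = Field(ge=0)
    body: BodyOutline
    spheres: list[SphereSpec]

    @model_validator(mode="after")
    def _check_spheres_inside(self) -> "PhantomSpec":
        for s in self.spheres:
            x, y, z = s.center_mm
            if float(self.body.sdf(x, y, z)) + s.radius_mm >= 0.0:
                raise ValueError(
                    f"sphere {s.label!r} extends outside the body outline"
                )
        return self

    def sphere_by_diameter(self, diameter_mm: float) -> SphereSpec:
        for s in self.spheres:
            if abs(s.inner_diameter_mm - diameter_mm) < 1e-9:
                return s
        raise KeyError(f"no sphere with diameter {diameter_mm} mm in {self.name!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        return cls.model_validate_json(Path(path).read_text())


def _standard_spheres(
    sphere_kbq_per_ml: float = DEFAULT_SPHERE_KBQ_PER_ML,
) -> list[SphereSpec]:
    """Six NEMA spheres on the standard transaxial ring, largest at 0 deg,
    then every 60 deg in order of decreasing diameter."""
    spheres = []
    for k, d in enumerate(NEMA_SPHERE_DIAMETERS_MM):
        ang = math.radians(60.0 * k)
        cx = SPHERE_RING_RADIUS_MM * math.cos(ang)
        cy = SPHERE_RING_RADIUS_MM * math.sin(ang)
        spheres.append(
            SphereSpec(
                label=f"sphere_{d:.0f}mm",
                inner_diameter_mm=d,
                center_mm=(cx, cy, 0.0),
                activity_kbq_per_ml=sphere_kbq_per_ml,
            )
        )
    return spheres


# (name, total volume l, waist circumference cm, BMI kg/m^2)
_STANDARD_PHANTOM_TABLE = (
    ("small", 9.70, 85.0, 25.0),
    ("medium", 14.73, 100.0, 28.0),
    ("large", 25.96, 130.0, 47.0),
)


def build_standard_phantoms(
    background_kbq_per_ml: float = DEFAULT_BACKGROUND_KBQ_PER_ML,
    sphere_kbq_per_ml: float = DEFAULT_SPHERE_KBQ_PER_ML,
) -> list[PhantomSpec]:
    """The small (standard NEMA) phantom plus the two enlarged-BMI variants.

    The small phantom uses the NEMA interior cross-section (300 x 230 mm)
    with the axial length chosen so the outline volume matches 9.70 l.  The
    enlarged phantoms scale the cross-section isotropically so its perimeter
    matches the stated waist circumference, then set the axial length to
    match the stated volume.  All variants carry the same six spheres at a
    10:1 sphere-to-background concentration ratio.
    """
    base = BodyOutline(width_mm=NEMA_BODY_WIDTH_MM, height_mm=NEMA_BODY_HEIGHT_MM, length_mm=1.0)
    specs = []
    for name, vol_l, waist_cm, bmi in _STANDARD_PHANTOM_TABLE:
        if name == "small":
            w, h = NEMA_BODY_WIDTH_MM, NEMA_BODY_HEIGHT_MM
        else:
            scale = (waist_cm * 10.0) / base.perimeter_mm
            w, h = NEMA_BODY_WIDTH_MM * scale, NEMA_BODY_HEIGHT_MM * scale
        outline = BodyOutline(width_mm=w, height_mm=h, length_mm=1.0)
        length = vol_l * 1e6 / outline.cross_section_area_mm2
        specs.append(
            PhantomSpec(
                name=name,
                total_volume_l=vol_l,
                waist_circumference_cm=waist_cm,
                bmi_kg_m2=bmi,
                background_kbq_per_ml=background_kbq_per_ml,
                body=BodyOutline(width_mm=w, height_mm=h, length_mm=length),
                spheres=_standard_spheres(sphere_kbq_per_ml),
            )
        )
    return specs


def grid_axis_coords(n: int, voxel_mm: float) -> np.ndarray:
    """Voxel-center coordinates for an axis of ``n`` voxels centred on 0.

    Computed as ``(k - (n-1)/2) * h`` so the coordinate array is exactly
    symmetric under negation, which makes mirrored phantoms rasterize to
    mirrored grids voxel-exactly.
    """
    return (np.arange(n) - (n - 1) / 2.0) * voxel_mm


@dataclass
class ActivityMap:
    """A 3D activity-concentration map (kBq/ml) on a regular voxel grid.

    ``grid`` is indexed (x, y, z); ``origin_mm`` is the world position of
    the center of voxel (0, 0, 0).
    """

    grid: np.ndarray
    voxel_size_mm: np.ndarray
    origin_mm: np.ndarray

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


def _as_voxel_vector(voxel_size_mm) -> np.ndarray:
    v = np.atleast_1d(np.asarray(voxel_size_mm, dtype=float))
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.size != 3 or np.any(v <= 0):
        raise ValueError(f"voxel size must be a positive scalar or 3-vector, got {voxel_size_mm}")
    return v


def voxelize(
    spec: PhantomSpec,
    voxel_size_mm,
    subsamples_per_axis: int = 5,
    pad_mm: float = 20.0,
    chunk_voxels: int = 20000,
) -> ActivityMap:
    """Rasterize a phantom into a partial-volume-accurate activity map.

    Each voxel's value is the volume-weighted mean concentration of the
    materials it intersects.  Voxels whose center is farther than half the
    voxel diagonal from every material interface are classified analytically
    (exact compartment concentration); interface voxels are resolved by
    regular sub-voxel sampling (``subsamples_per_axis`` per axis at the body
    wall; sphere surfaces are sampled at least ten times per smallest sphere
    radius).  Voxels fully outside the body are zero.
    """
    if subsamples_per_axis < 1:
        raise ValueError("subsamples_per_axis must be >= 1")
    h = _as_voxel_vector(voxel_size_mm)
    body = spec.body

    for s in spec.spheres:
        x, y, z = s.center_mm
        if float(body.sdf(x, y, z)) + s.radius_mm >= 0.0:
            raise GeometryError(f"sphere {s.label!r} extends outside the body outline")

    extent = np.array([body.width_mm, body.height_mm, body.length_mm]) + 2.0 * pad_mm
    n = np.ceil(extent / h).astype(int)
    cx, cy, cz = (grid_axis_coords(n[i], h[i]) for i in range(3))
    origin = np.array([cx[0], cy[0], cz[0]])

    half_diag = 0.5 * float(np.linalg.norm(h))

    d2d = body.sdf2d(cx[:, None], cy[None, :])  # (nx, ny)
    body_sdf = np.maximum(d2d[:, :, None], np.abs(cz)[None, None, :] - 0.5 * body.length_mm)

    value = np.zeros(tuple(n), dtype=float)
    value[body_sdf < 0] = spec.background_kbq_per_ml
    amb_body = np.abs(body_sdf) <= half_diag
    amb_sphere = np.zeros(tuple(n), dtype=bool)

    for s in spec.spheres:
        dist = np.sqrt(
            ((cx - s.center_mm[0]) ** 2)[:, None, None]
            + ((cy - s.center_mm[1]) ** 2)[None, :, None]
            + ((cz - s.center_mm[2]) ** 2)[None, None, :]
        )
        value[dist < s.radius_mm] = s.activity_kbq_per_ml
        amb_sphere |= np.abs(dist - s.radius_mm) <= half_diag

    # Sphere surfaces are refined at a sample spacing of at most a tenth of
    # the smallest sphere radius so that coarse grids (voxels comparable to
    # the smallest sphere) still integrate sphere activity to < 1%.
    ns_body = subsamples_per_axis
    if spec.spheres and ns_body > 1:
        r_min = min(s.radius_mm for s in spec.spheres)
        ns_sphere = max(ns_body, int(np.ceil(float(np.max(h)) / (r_min / 10.0))))
    else:
        # subsamples_per_axis == 1 requests hard-edged center classification
        ns_sphere = ns_body

    def _refine(idx: np.ndarray, ns: int) -> None:
        if idx.size == 0:
            return
        m = (np.arange(ns) + 0.5) - ns / 2.0  # symmetric half-integer offsets
        off = np.stack(
            np.meshgrid(m * h[0] / ns, m * h[1] / ns, m * h[2] / ns, indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        centers = np.stack([cx[idx[:, 0]], cy[idx[:, 1]], cz[idx[:, 2]]], axis=1)
        total = ns**3
        chunk = max(1, chunk_voxels * subsamples_per_axis**3 // total)
        refined = np.empty(len(idx), dtype=float)
        for lo in range(0, len(idx), chunk):
            sl = slice(lo, lo + chunk)
            pts = centers[sl][:, None, :] + off[None, :, :]  # (B, ns^3, 3)
            in_body = body.sdf(pts[..., 0], pts[..., 1], pts[..., 2]) < 0
            covered = np.zeros(in_body.shape, dtype=bool)
            acc = np.zeros(pts.shape[0], dtype=float)
            for s in spec.spheres:
                c = np.asarray(s.center_mm)
                d2 = ((pts - c) ** 2).sum(axis=-1)
                ins = d2 <= s.radius_mm**2
                acc += ins.sum(axis=1) * s.activity_kbq_per_ml
                covered |= ins
            bg_n = (in_body & ~covered).sum(axis=1)
            refined[sl] = (acc + bg_n * spec.background_kbq_per_ml) / total
        value[idx[:, 0], idx[:, 1], idx[:, 2]] = refined

    _refine(np.argwhere(amb_body & ~amb_sphere), ns_body)
    _refine(np.argwhere(amb_sphere), ns_sphere)

    return ActivityMap(grid=value, voxel_size_mm=h, origin_mm=origin)
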