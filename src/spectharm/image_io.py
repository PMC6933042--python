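"""Image I/O: activity maps and quantitative images as NIfTI / MetaImage.

Quantitative images carry a JSON sidecar (same stem, ``.json``) recording
the unit tag, acquisition settings, seed and system-profile name, since
neither NIfTI nor MetaImage headers have standard fields for these.
Arrays are stored internally as (x, y, z); SimpleITK's (z, y, x) layout is
handled transparently here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .phantom_geometry import ActivityMap
from .simulator import AcquisitionSettings, QuantImage

__all__ = [
    "write_activity_map",
    "read_activity_map",
    "write_quant_image",
    "read_quant_image",
    "sidecar_path",
]

_SUPPORTED = (".nii.gz", ".nii", ".mha", ".mhd")


def _check_ext(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _SUPPORTED):
        raise ValueError(f"unsupported image format for {path.name!r}; use one of {_SUPPORTED}")


def _strip_ext(path: Path) -> Path:
    name = path.name
    for ext in _SUPPORTED:
        if name.lower().endswith(ext):
            return path.with_name(name[: -len(ext)])
    return path.with_suffix("")


def sidecar_path(image_path: str | Path) -> Path:
    return _strip_ext(Path(image_path)).with_suffix(".json")


def _to_sitk(grid: np.ndarray, voxel_size_mm, origin_mm) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(grid).transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(v) for v in voxel_size_mm))
    img.SetOrigin(tuple(float(v) for v in origin_mm))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    grid = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
    return grid, np.asarray(img.GetSpacing(), float), np.asarray(img.GetOrigin(), float)


def write_activity_map(amap: ActivityMap, path: str | Path) -> None:
    path = Path(path)
    _check_ext(path)
    sitk.WriteImage(_to_sitk(amap.grid, amap.voxel_size_mm, amap.origin_mm), str(path))


def read_activity_map(path: str | Path) -> ActivityMap:
    grid, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return ActivityMap(grid=grid, voxel_size_mm=spacing, origin_mm=origin)


def write_quant_image(image: QuantImage, path: str | Path) -> None:
    path = Path(path)
    _check_ext(path)
    sitk.WriteImage(_to_sitk(image.grid, image.voxel_size_mm, image.origin_mm), str(path))
    meta = {
        "unit": image.unit,
        "profile_name": image.profile_name,
        "settings": image.settings.model_dump(),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_quant_image(path: str | Path) -> QuantImage:
    path = Path(path)
    grid, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing sidecar {sc.name!r} for quantitative image {path.name!r}")
    meta = json.loads(sc.read_text())
    return QuantImage(
        grid=grid,
        voxel_size_mm=spacing,
        origin_mm=origin,
        unit=meta["unit"],
        settings=AcquisitionSettings.model_validate(meta["settings"]),
        profile_name=meta.get("profile_name", ""),
    )
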