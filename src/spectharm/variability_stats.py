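"""MAD-based repeatability and inter-system variability statistics.

Dispersion is summarized with the median absolute deviation

    MAD = median(|RC_i - median(RC)|),

a robust alternative to the standard deviation (reported unscaled, i.e.
without the 1.4826 normal-consistency factor).  Repeatability is the MAD of
a sphere's RC across repeated acquisitions on one system; inter-system
variability is, per sphere, the MAD across the per-system median RCs.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "mad",
    "records_frame",
    "per_sphere_repeatability",
    "repeatability_table",
    "intersystem_table",
    "summarize_mad_columns",
    "round_half_up",
]

logger = logging.getLogger(__name__)

METRICS = ("rc_mean", "rc_max")


def mad(values: Iterable[float]) -> float:
    """Median absolute deviation from the median.

    Even-length medians are the midpoint of the two central order
    statistics (the numpy convention).
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if arr.size == 0:
        raise ValueError("mad() requires a non-empty list of values")
    med = np.median(arr)
    return float(np.median(np.abs(arr - med)))


def records_frame(records) -> pd.DataFrame:
    """Normalize RC records (dataclasses or a DataFrame) to a tidy frame,
    dropping rows whose RC values are missing (unsegmentable spheres)."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "system": r.system,
                "phantom": r.phantom,
                "replicate": r.replicate,
                "sphere_diameter_mm": r.sphere_diameter_mm,
                "rc_mean": r.rc_mean,
                "rc_max": r.rc_max,
                "voi_volume_ml": r.voi_volume_ml,
            }
            for r in records
        )
    return df.dropna(subset=["rc_mean", "rc_max"])


def per_sphere_repeatability(records) -> pd.DataFrame:
    """Per (system, phantom, sphere, metric): MAD across replicates.

    Groups with fewer than two replicates are skipped with a warning.
    """
    df = records_frame(records)
    rows = []
    for (system, phantom, d), grp in df.groupby(["system", "phantom", "sphere_diameter_mm"]):
        if len(grp) < 2:
            logger.warning(
                "skipping repeatability for system=%s phantom=%s sphere=%g mm: "
                "only %d replicate(s)",
                system, phantom, d, len(grp),
            )
            continue
        for metric in METRICS:
            vals = grp[metric].to_numpy()
            rows.append(
                {
                    "system": system,
                    "phantom": phantom,
                    "sphere_diameter_mm": d,
                    "metric": metric,
                    "mad": mad(vals),
                    "median_rc": float(np.median(vals)),
                    "n_values": len(vals),
                }
            )
    return pd.DataFrame(rows)


def repeatability_table(records) -> pd.DataFrame:
    """Per-system repeatability summary: the median and range of the
    per-sphere MADs over sphere diameters, for each metric."""
    per_sphere = per_sphere_repeatability(records)
    rows = []
    if per_sphere.empty:
        return pd.DataFrame(
            columns=["system", "phantom", "metric", "mad_median", "mad_min", "mad_max", "n_spheres"]
        )
    for (system, phantom, metric), grp in per_sphere.groupby(["system", "phantom", "metric"]):
        mads = grp["mad"].to_numpy()
        rows.append(
            {
                "system": system,
                "phantom": phantom,
                "metric": metric,
                "mad_median": float(np.median(mads)),
                "mad_min": float(np.min(mads)),
                "mad_max": float(np.max(mads)),
                "n_spheres": len(mads),
            }
        )
    return pd.DataFrame(rows)


def intersystem_table(records, reducer=np.median) -> pd.DataFrame:
    """Per-sphere inter-system variability.

    For each sphere diameter and metric the per-system RCs are first reduced
    over replicates (median by default), then the MAD is taken across the
    per-system values.  Relative MADs are reported as 100*MAD/median_RC and
    are a derived convenience, not a primary output.
    """
    df = records_frame(records)
    if df["system"].nunique() < 2:
        raise ValueError("inter-system variability requires records from >= 2 systems")
    rows = []
    for (phantom, d), grp in df.groupby(["phantom", "sphere_diameter_mm"]):
        for metric in METRICS:
            per_system = (
                grp.groupby("system")[metric].apply(lambda v: float(reducer(v))).sort_index()
            )
            if len(per_system) < 2:
                continue
            m = mad(per_system.to_numpy())
            med = float(np.median(per_system.to_numpy()))
            rows.append(
                {
                    "phantom": phantom,
                    "sphere_diameter_mm": d,
                    "metric": metric,
                    "mad": m,
                    "median_rc": med,
                    "mad_pct": 100.0 * m / med if med > 0 else float("nan"),
                    "n_systems": len(per_system),
                }
            )
    return pd.DataFrame(rows)


def summarize_mad_columns(per_sphere_mads: Iterable[float]) -> dict[str, float]:
    """Median, minimum and maximum of a column of per-sphere MAD values."""
    arr = np.asarray(list(per_sphere_mads), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize_mad_columns() requires a non-empty list")
    return {
        "median": float(np.median(arr)),
        "min": float(np.min(arr)),
        "max": float(np.max(arr)),
    }


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero, matching report-table presentation."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
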