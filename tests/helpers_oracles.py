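"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: an explicit
sort-based MAD, a closed-form radial profile of a Gaussian-blurred uniform
sphere, and fine-grid brute-force rasterization.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf


def brute_force_mad(values) -> float:
    """Median absolute deviation via explicit sorting (no numpy.median)."""

    def _median(xs):
        xs = sorted(xs)
        n = len(xs)
        mid = n // 2
        if n % 2 == 1:
            return xs[mid]
        return 0.5 * (xs[mid - 1] + xs[mid])

    med = _median(list(values))
    return _median([abs(v - med) for v in values])


def blurred_sphere_profile(r, radius_mm, sigma_mm, inner, outer):
    """Value at radial distance r from the center of a uniform sphere
    (value ``inner``) on a uniform background (``outer``) after isotropic
    Gaussian blurring; standard closed form."""
    r = np.asarray(r, dtype=float)
    R, s = radius_mm, sigma_mm
    rr = np.where(r < 1e-9, 1e-9, r)
    a = (R - r) / (np.sqrt(2.0) * s)
    b = (R + r) / (np.sqrt(2.0) * s)
    f = 0.5 * (erf(a) + erf(b)) - s / (np.sqrt(2.0 * np.pi) * rr) * (
        np.exp(-((R - rr) ** 2) / (2.0 * s**2)) - np.exp(-((R + rr) ** 2) / (2.0 * s**2))
    )
    return outer + (inner - outer) * f


def oracle_threshold_radius(radius_mm, sigma_mm, inner, outer, step_mm=0.01):
    """Radius of the iso-surface at the background-corrected half-maximum
    threshold of the analytic blurred-sphere profile, by fine radial search.

    Returns (threshold, iso_radius_mm, enclosed_volume_ml).
    """
    peak = float(blurred_sphere_profile(0.0, radius_mm, sigma_mm, inner, outer))
    threshold = 0.5 * (peak + outer)
    r = np.arange(step_mm, radius_mm + 6.0 * sigma_mm, step_mm)
    vals = blurred_sphere_profile(r, radius_mm, sigma_mm, inner, outer)
    above = np.nonzero(vals >= threshold)[0]
    iso_r = float(r[above[-1]]) if above.size else 0.0
    volume_ml = 4.0 / 3.0 * np.pi * iso_r**3 * 1e-3
    return threshold, iso_r, volume_ml


def brute_force_sphere_volume_ml(radius_mm, step_mm=0.2) -> float:
    """Sphere volume by counting fine-grid points inside (0.2 mm default)."""
    n = int(np.ceil(2.0 * radius_mm / step_mm)) + 3
    c = (np.arange(n) - (n - 1) / 2.0) * step_mm
    X, Y = np.meshgrid(c, c, indexing="ij")
    d2 = X**2 + Y**2
    count = 0
    for z in c:  # slab-wise to bound memory
        count += int(np.count_nonzero(d2 + z**2 <= radius_mm**2))
    return count * step_mm**3 * 1e-3
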