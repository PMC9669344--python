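"""Intensity-based statistics: 18 first-order statistics + 2 intensity peaks.

All statistics are computed over the masked voxels without discretization.
Degenerate-input policy: on a constant region, skewness, kurtosis and the
coefficient of variation are set to 0 so downstream design matrices stay
finite.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .lesion import LesionImage

# Catalog order for this family.
INTENSITY_FEATURES = [
    "stat_mean",
    "stat_variance",
    "stat_skewness",
    "stat_kurtosis",
    "stat_median",
    "stat_minimum",
    "stat_p10",
    "stat_p90",
    "stat_maximum",
    "stat_interquartile_range",
    "stat_range",
    "stat_mean_absolute_deviation",
    "stat_robust_mean_absolute_deviation",
    "stat_median_absolute_deviation",
    "stat_coefficient_of_variation",
    "stat_quartile_coefficient_of_dispersion",
    "stat_energy",
    "stat_root_mean_square",
    "stat_local_intensity_peak",
    "stat_global_intensity_peak",
]

# Radius (mm) of the 1 cm^3 sphere used by the intensity-peak features.
_PEAK_RADIUS_MM = (3.0 / (4.0 * np.pi) * 1000.0) ** (1.0 / 3.0)


def _sphere_means(lesion: LesionImage) -> np.ndarray:
    """Mean masked intensity in a 1 cm^3 sphere centred at every voxel.

    The sphere kernel is built in voxel units from the physical spacing; a
    voxel belongs to the kernel when its centre lies within the radius.  The
    mean is taken over kernel voxels inside the lesion mask, which makes the
    peak features intrinsic to the lesion (independent of how much scan
    context surrounds the crop).
    """
    radii = [max(1, int(np.floor(_PEAK_RADIUS_MM / s))) for s in lesion.spacing]
    grids = np.meshgrid(
        *[np.arange(-r, r + 1) * s for r, s in zip(radii, lesion.spacing)], indexing="ij"
    )
    dist2 = sum(g**2 for g in grids)
    kernel = (dist2 <= _PEAK_RADIUS_MM**2).astype(float)
    inmask = np.where(lesion.mask, lesion.intensity, 0.0)
    ssum = ndimage.convolve(inmask, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(
        lesion.mask.astype(float), kernel, mode="constant", cval=0.0
    )
    out = np.full(lesion.intensity.shape, np.nan)
    ok = counts > 0
    out[ok] = ssum[ok] / counts[ok]
    return out


def intensity_statistics(lesion: LesionImage) -> dict[str, float]:
    """Compute the 20 intensity-based statistics for one lesion."""
    x = lesion.values
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = np.sqrt(var)
    centred = x - mean
    if sd > 0:
        skew = float((centred**3).mean() / sd**3)
        kurt = float((centred**4).mean() / sd**4 - 3.0)  # excess kurtosis
        cov = sd / mean if mean != 0 else 0.0
    else:
        skew = kurt = cov = 0.0

    p10, q1, med, q3, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    qcd = (q3 - q1) / (q3 + q1) if (q3 + q1) != 0 else 0.0

    sphere = _sphere_means(lesion)
    masked_sphere = sphere[lesion.mask]
    # Local peak: sphere mean at the maximum-intensity voxel (highest sphere
    # mean when the maximum is attained at several voxels).
    at_max = masked_sphere[x == x.max()]
    local_peak = float(at_max.max())
    global_peak = float(masked_sphere.max())

    return {
        "stat_mean": mean,
        "stat_variance": var,
        "stat_skewness": skew,
        "stat_kurtosis": kurt,
        "stat_median": float(med),
        "stat_minimum": float(x.min()),
        "stat_p10": float(p10),
        "stat_p90": float(p90),
        "stat_maximum": float(x.max()),
        "stat_interquartile_range": float(q3 - q1),
        "stat_range": float(x.max() - x.min()),
        "stat_mean_absolute_deviation": float(np.abs(centred).mean()),
        "stat_robust_mean_absolute_deviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "stat_median_absolute_deviation": float(np.abs(x - med).mean()),
        "stat_coefficient_of_variation": float(cov),
        "stat_quartile_coefficient_of_dispersion": float(qcd),
        "stat_energy": float((x**2).sum()),
        "stat_root_mean_square": float(np.sqrt((x**2).mean())),
        "stat_local_intensity_peak": local_peak,
        "stat_global_intensity_peak": global_peak,
    }
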