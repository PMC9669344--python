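"""Intensity-histogram (23) and intensity-volume-histogram (7) features.

The histogram family works on discretized grey levels 1..Ng; the IVH family
works on the continuous masked intensities.  Single-level histograms follow
the degenerate policy: entropy 0, uniformity 1, moments 0.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizationConfig, discretize
from .lesion import LesionImage

HISTOGRAM_FEATURES = [
    "hist_mean",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
    "hist_median",
    "hist_minimum",
    "hist_p10",
    "hist_p90",
    "hist_maximum",
    "hist_mode",
    "hist_interquartile_range",
    "hist_range",
    "hist_mean_absolute_deviation",
    "hist_robust_mean_absolute_deviation",
    "hist_median_absolute_deviation",
    "hist_coefficient_of_variation",
    "hist_quartile_coefficient_of_dispersion",
    "hist_entropy",
    "hist_uniformity",
    "hist_max_gradient",
    "hist_max_gradient_level",
    "hist_min_gradient",
    "hist_min_gradient_level",
    "ivh_volume_at_intensity_10",
    "ivh_volume_at_intensity_90",
    "ivh_intensity_at_volume_10",
    "ivh_intensity_at_volume_90",
    "ivh_volume_fraction_difference",
    "ivh_intensity_difference",
    "ivh_area_under_curve",
]


def _histogram_stats(levels: np.ndarray) -> dict[str, float]:
    g = levels.astype(float)
    ng = int(levels.max())
    counts = np.bincount(levels, minlength=ng + 1)[1:].astype(float)
    p = counts / counts.sum()
    mean = g.mean()
    var = g.var()
    sd = np.sqrt(var)
    centred = g - mean
    if sd > 0:
        skew = float((centred**3).mean() / sd**3)
        kurt = float((centred**4).mean() / sd**4 - 3.0)
        cov = sd / mean if mean != 0 else 0.0
    else:
        skew = kurt = cov = 0.0
    p10, q1, med, q3, p90 = np.percentile(g, [10, 25, 50, 75, 90])
    robust = g[(g >= p10) & (g <= p90)]
    nonzero = p[p > 0]
    entropy = float(-(nonzero * np.log2(nonzero)).sum())
    # Histogram gradient over occupancy fractions; a single-level histogram
    # has zero gradient by convention.
    if ng > 1:
        grad = np.gradient(counts)
        imax, imin = int(np.argmax(grad)), int(np.argmin(grad))
        max_grad, min_grad = float(grad[imax]), float(grad[imin])
        max_grad_level, min_grad_level = float(imax + 1), float(imin + 1)
    else:
        max_grad = min_grad = 0.0
        max_grad_level = min_grad_level = 1.0
    return {
        "hist_mean": float(mean),
        "hist_variance": float(var),
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_median": float(med),
        "hist_minimum": float(g.min()),
        "hist_p10": float(p10),
        "hist_p90": float(p90),
        "hist_maximum": float(g.max()),
        "hist_mode": float(np.argmax(counts) + 1),
        "hist_interquartile_range": float(q3 - q1),
        "hist_range": float(g.max() - g.min()),
        "hist_mean_absolute_deviation": float(np.abs(centred).mean()),
        "hist_robust_mean_absolute_deviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "hist_median_absolute_deviation": float(np.abs(g - med).mean()),
        "hist_coefficient_of_variation": float(cov),
        "hist_quartile_coefficient_of_dispersion": float(
            (q3 - q1) / (q3 + q1) if (q3 + q1) != 0 else 0.0
        ),
        "hist_entropy": entropy,
        "hist_uniformity": float((p**2).sum()),
        "hist_max_gradient": max_grad,
        "hist_max_gradient_level": max_grad_level,
        "hist_min_gradient": min_grad,
        "hist_min_gradient_level": min_grad_level,
    }


def _ivh_features(values: np.ndarray) -> dict[str, float]:
    """Intensity-volume-histogram features on continuous intensities.

    nu(gamma) is the fraction of lesion volume with intensity at least
    ``min + gamma * range``; a constant lesion has nu == 1 everywhere.
    """
    lo, hi = float(values.min()), float(values.max())
    n = values.size

    def vol_frac_at(gamma: float) -> float:
        if hi == lo:
            return 1.0
        thr = lo + gamma * (hi - lo)
        return float((values >= thr).sum() / n)

    def intensity_at_volume(frac: float) -> float:
        # Smallest intensity present in the top `frac` of lesion volume.
        if hi == lo:
            return hi
        return float(np.quantile(values, 1.0 - frac))

    v10, v90 = vol_frac_at(0.10), vol_frac_at(0.90)
    i10, i90 = intensity_at_volume(0.10), intensity_at_volume(0.90)
    gammas = np.linspace(0.0, 1.0, 1001)
    auc = float(np.trapezoid([vol_frac_at(g) for g in gammas], gammas))
    return {
        "ivh_volume_at_intensity_10": v10,
        "ivh_volume_at_intensity_90": v90,
        "ivh_intensity_at_volume_10": i10,
        "ivh_intensity_at_volume_90": i90,
        "ivh_volume_fraction_difference": v10 - v90,
        "ivh_intensity_difference": i10 - i90,
        "ivh_area_under_curve": auc,
    }


def histogram_features(
    lesion: LesionImage, cfg: DiscretizationConfig | None = None
) -> dict[str, float]:
    """Compute the 30 histogram-family features (23 histogram + 7 IVH)."""
    cfg = cfg or DiscretizationConfig()
    levels = discretize(lesion, cfg)[lesion.mask]
    out = _histogram_stats(levels)
    out.update(_ivh_features(lesion.values))
    return out
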