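"""Spatial-distribution features: 27 values per scan from an atlas-labeled
lesion mask.

The vector is: 16 per-region lesion-voxel counts (12 supratentorial + 4
infratentorial region labels), the lesion count, mean/maximum/summed lesion
sizes in mm^3, and the lesion count within seven half-open size ranges
[8, 80), [80, 160), [160, 320), [320, 640), [640, 1280), [1280, 2560) and
[2560, inf) mm^3.  Lesion instances are 26-connected components; components
below 8 mm^3 are discarded (mirroring the segmentation rule that ignores
tiny lesions), which makes the bin counts total the lesion count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

N_REGIONS = 16
SIZE_BINS_MM3 = (8.0, 80.0, 160.0, 320.0, 640.0, 1280.0, 2560.0)
MIN_COMPONENT_MM3 = 8.0

SPATIAL_FEATURES = (
    [f"region_{i:02d}_voxels" for i in range(1, N_REGIONS + 1)]
    + ["lesion_count", "mean_lesion_size", "max_lesion_size", "summed_lesion_size"]
    + [
        "n_lesions_8_80",
        "n_lesions_80_160",
        "n_lesions_160_320",
        "n_lesions_320_640",
        "n_lesions_640_1280",
        "n_lesions_1280_2560",
        "n_lesions_over_2560",
    ]
)


@dataclass
class LabeledScanMask:
    """A scan's binary lesion mask plus the 16-region atlas it lives in."""

    mask: np.ndarray
    atlas: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.atlas = np.asarray(self.atlas).astype(int)
        if self.mask.shape != self.atlas.shape:
            raise ValueError("mask and atlas grids must be congruent")
        labels = set(np.unique(self.atlas)) - {0}
        if not labels <= set(range(1, N_REGIONS + 1)):
            raise ValueError(f"atlas labels must lie in 0..{N_REGIONS}, got {sorted(labels)}")


def binarize_mask(prob_mask: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize a probabilistic lesion mask: included iff value >= threshold.

    The 0.5 default avoids lesion expansion introduced by interpolation into
    atlas space; values must lie in [0, 1].
    """
    prob_mask = np.asarray(prob_mask, dtype=float)
    if (prob_mask < 0).any() or (prob_mask > 1).any():
        raise ValueError("probabilistic mask values must lie in [0, 1]")
    return prob_mask >= threshold


def label_components(
    mask: np.ndarray, spacing: tuple[float, float, float]
) -> tuple[np.ndarray, list[float]]:
    """Lesion instancing: 26-connected components with sizes in mm^3.

    Components smaller than 8 mm^3 are removed from the returned label grid
    and size list (logged as a warning).  Returns (labelled grid, sizes);
    labels are 1..n in decreasing-size-independent scan order.
    """
    mask = np.asarray(mask).astype(bool)
    voxvol = float(np.prod(spacing))
    structure = np.ones((3, 3, 3), dtype=int)
    lab, nlab = ndimage.label(mask, structure=structure)
    if nlab == 0:
        return lab, []
    counts = np.bincount(lab.ravel())[1:]
    sizes = counts * voxvol
    keep = sizes >= MIN_COMPONENT_MM3
    if (~keep).any():
        warnings.warn(
            f"discarding {(~keep).sum()} lesion component(s) below "
            f"{MIN_COMPONENT_MM3} mm^3",
            stacklevel=2,
        )
    relabel = np.zeros(nlab + 1, dtype=int)
    relabel[1:][keep] = np.arange(1, keep.sum() + 1)
    return relabel[lab], sizes[keep].tolist()


@dataclass
class SpatialFeatureVector:
    """The 27 spatial-distribution values for one scan."""

    values: np.ndarray
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(SPATIAL_FEATURES),):
            raise ValueError(f"spatial vector must have {len(SPATIAL_FEATURES)} values")
        if (self.values < 0).any():
            raise ValueError("spatial features are all non-negative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=SPATIAL_FEATURES, name=self.subject_id)


def spatial_vector(scan: LabeledScanMask) -> SpatialFeatureVector:
    """Compute the 27 spatial-distribution features of one scan."""
    lab, sizes = label_components(scan.mask, scan.spacing)
    kept = lab > 0
    region_counts = np.zeros(N_REGIONS)
    if kept.any():
        atlas_vals = scan.atlas[kept]
        on_background = int((atlas_vals == 0).sum())
        if on_background:
            warnings.warn(
                f"{on_background} lesion voxel(s) lie on atlas background; "
                "counted in size statistics but not in region counts",
                stacklevel=2,
            )
        counts = np.bincount(atlas_vals, minlength=N_REGIONS + 1)
        region_counts = counts[1:].astype(float)
    sizes_arr = np.asarray(sizes, dtype=float)
    n = len(sizes_arr)
    mean_size = float(sizes_arr.mean()) if n else 0.0
    max_size = float(sizes_arr.max()) if n else 0.0
    sum_size = float(sizes_arr.sum()) if n else 0.0
    edges = list(SIZE_BINS_MM3) + [np.inf]
    bins = [
        float(((sizes_arr >= lo) & (sizes_arr < hi)).sum())
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    values = np.concatenate(
        [region_counts, [float(n), mean_size, max_size, sum_size], bins]
    )
    return SpatialFeatureVector(values, scan.subject_id)


def spatial_table(scans: list[LabeledScanMask]) -> pd.DataFrame:
    """Stack per-scan spatial vectors into a table keyed by subject_id."""
    rows = []
    for scan in scans:
        row = {"subject_id": scan.subject_id}
        row.update(spatial_vector(scan).as_series().to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
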