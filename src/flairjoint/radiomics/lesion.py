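"""Lesion container: an intensity patch, its binary mask and the voxel spacing.

A :class:`LesionImage` is the unit every radiomics family operates on.  It is
deliberately grid-agnostic: callers crop a connected lesion component (plus a
small margin, so that intensity-peak kernels have context) out of a scan and
hand it over together with the physical voxel spacing in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LesionImage:
    """One lesion: intensity voxels, binary mask, and voxel spacing (mm).

    Parameters
    ----------
    intensity : (nx, ny, nz) float array
        Intensity values; only values inside ``mask`` must be finite.
    mask : (nx, ny, nz) bool array
        Non-empty binary lesion mask, congruent with ``intensity``.
    spacing : length-3 sequence of float
        Voxel edge lengths in mm, all positive.
    lesion_id, subject_id : str
        Identifiers carried through to feature tables.
    """

    intensity: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_id: str = "lesion"
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.intensity.ndim != 3 or self.mask.ndim != 3:
            raise ValueError("intensity and mask must be 3-D arrays")
        if self.intensity.shape != self.mask.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != mask shape {self.mask.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not self.mask.any():
            raise ValueError(f"lesion {self.lesion_id!r}: mask is empty")
        if not np.isfinite(self.intensity[self.mask]).all():
            raise ValueError(f"lesion {self.lesion_id!r}: non-finite intensity inside mask")

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def values(self) -> np.ndarray:
        """Masked intensity values, flattened."""
        return self.intensity[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())
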