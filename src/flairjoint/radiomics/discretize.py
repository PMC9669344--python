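"""Grey-level discretization of lesion intensities.

Texture and histogram families operate on integer grey levels 1..Ng.  Two
standard schemes are supported:

* ``fixed-bin-number`` — the masked intensity range [min, max] is split into
  N equal bins; the maximum maps to level N.  Scale- and shift-invariant,
  which suits synthetic intensity units; this is the package default (N=64).
* ``fixed-bin-size`` — bins of a fixed width anchored at the masked minimum.

A constant region maps to level 1 under either scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lesion import LesionImage

METHODS = ("fixed-bin-number", "fixed-bin-size")


@dataclass(frozen=True)
class DiscretizationConfig:
    """Discretization scheme: ``method`` and its parameter.

    For ``fixed-bin-number`` the parameter is the bin count (int >= 1);
    for ``fixed-bin-size`` it is the bin width (> 0).
    """

    method: str = "fixed-bin-number"
    parameter: float = 64

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.parameter <= 0:
            raise ValueError(f"parameter must be > 0, got {self.parameter}")
        if self.method == "fixed-bin-number" and int(self.parameter) != self.parameter:
            raise ValueError("fixed-bin-number requires an integer bin count")


def discretize(lesion: LesionImage, cfg: DiscretizationConfig) -> np.ndarray:
    """Map masked intensities to integer grey levels >= 1; 0 outside the mask.

    Fixed-bin-number with N bins maps ``[min, max]`` onto ``1..N`` via
    ``floor(N * (x - min) / (max - min)) + 1`` capped at N; a constant region
    maps to level 1.
    """
    values = lesion.values
    lo = values.min()
    hi = values.max()
    levels = np.zeros(lesion.mask.shape, dtype=np.int64)
    if cfg.method == "fixed-bin-number":
        n = int(cfg.parameter)
        if hi == lo:
            levels[lesion.mask] = 1
        else:
            scaled = np.floor(n * (values - lo) / (hi - lo)).astype(np.int64) + 1
            levels[lesion.mask] = np.minimum(scaled, n)
    else:  # fixed-bin-size
        width = float(cfg.parameter)
        levels[lesion.mask] = np.floor((values - lo) / width).astype(np.int64) + 1
    return levels
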