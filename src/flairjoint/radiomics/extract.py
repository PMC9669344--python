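"""Per-lesion feature extraction: one LesionImage -> one 351-value vector."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog
from .discretize import DiscretizationConfig, discretize
from .histogram import histogram_features
from .intensity import intensity_statistics
from .lesion import LesionImage
from .morphology import morphology_features
from .texture import texture_features


@dataclass
class FeatureVector:
    """Named radiomics values for one lesion, aligned to a catalog."""

    values: np.ndarray
    catalog: FeatureCatalog
    lesion_id: str
    subject_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.catalog),):
            raise ValueError(
                f"vector length {self.values.shape} != catalog length {len(self.catalog)}"
            )
        if not np.isfinite(self.values).all():
            bad = [
                self.catalog.feature_ids[i]
                for i in np.flatnonzero(~np.isfinite(self.values))
            ]
            raise ValueError(f"non-finite features for lesion {self.lesion_id!r}: {bad[:5]}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.catalog.feature_ids, name=self.lesion_id)


def extract_features(
    lesion: LesionImage,
    catalog: FeatureCatalog | None = None,
    cfg: DiscretizationConfig | None = None,
    slice_axis: int = 2,
) -> FeatureVector:
    """Extract the full 351-feature vector for one lesion.

    ``slice_axis`` selects the acquisition plane used by 2-D texture
    aggregations (default: last axis, the usual slice direction).
    """
    catalog = catalog or FeatureCatalog()
    cfg = cfg or DiscretizationConfig()
    try:
        feats: dict[str, float] = {}
        feats.update(morphology_features(lesion))
        feats.update(intensity_statistics(lesion))
        feats.update(histogram_features(lesion, cfg))
        levels = discretize(lesion, cfg)
        ng = int(levels.max())
        feats.update(texture_features(levels, ng, slice_axis=slice_axis))
    except Exception as err:  # re-raise with lesion context
        raise RuntimeError(
            f"feature extraction failed for subject {lesion.subject_id!r} "
            f"lesion {lesion.lesion_id!r}: {err}"
        ) from err
    values = np.array([feats[f] for f in catalog.feature_ids])
    return FeatureVector(values, catalog, lesion.lesion_id, lesion.subject_id)


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack per-lesion vectors into a table: subject_id, lesion_id + 351 columns."""
    if not vectors:
        raise ValueError("no feature vectors to tabulate")
    rows = []
    for v in vectors:
        row = {"subject_id": v.subject_id, "lesion_id": v.lesion_id}
        row.update(dict(zip(v.catalog.feature_ids, v.values)))
        rows.append(row)
    return pd.DataFrame(rows)
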