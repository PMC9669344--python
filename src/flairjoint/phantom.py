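"""Synthetic atlas-space phantom cohorts.

The generator emulates the two cohorts the analysis is designed around:

* **AE-like** scans carry several smaller lesions, frequently bilateral,
  preferentially placed in medial-temporal-like sectors of the synthetic
  atlas, with fine-grained (short correlation length), right-skewed texture.
* **AS-like** scans carry a single larger unilateral lesion weighted toward
  a frontal-like sector, with smoother (long correlation length) texture.

The "brain" is an ellipsoid partitioned deterministically into 12
supratentorial sectors (two axial bands x six angular sectors) and 4
infratentorial sectors (a ventral band x four angular sectors), labelled
1..12 and 13..16.  Lesions are thresholded smoothed random blobs seeded at a
sampled voxel of a sampled region — not perfect spheres — clipped to the
brain, so morphology features see non-trivial shapes.  Everything is
bit-reproducible from (config, class, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

N_REGIONS = 16


@dataclass
class ClassParams:
    """Lesion statistics of one phantom class.

    lesion_count_mean/dispersion parametrize a negative-binomial count
    (variance mean + mean^2/dispersion), truncated to >= 1; dispersion 0
    means a deterministic round(mean).  Radii are Gaussian in mm (clipped
    below at min_radius_mm).  placement_weights is a 16-vector over atlas
    regions.  Texture: intensity_offset above background, noise_sd, noise
    correlation_length_mm, and a skew factor shaping the histogram.
    """

    lesion_count_mean: float
    lesion_count_dispersion: float
    radius_mean_mm: float
    radius_sd_mm: float
    placement_weights: tuple[float, ...]
    intensity_offset: float = 30.0
    noise_sd: float = 10.0
    correlation_length_mm: float = 3.0
    intensity_skew: float = 0.0
    min_radius_mm: float = 2.5

    def __post_init__(self) -> None:
        w = np.asarray(self.placement_weights, dtype=float)
        if w.shape != (N_REGIONS,) or (w < 0).any():
            raise ValueError(f"placement_weights must be {N_REGIONS} non-negative values")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError(f"placement_weights must sum to 1, got {w.sum()}")
        if w.max() == 0:
            raise ValueError("degenerate placement distribution: zero everywhere")
        self.placement_weights = tuple(w.tolist())


def _default_ae_params() -> ClassParams:
    # bilateral medial-temporal-like emphasis: lower-band sectors 2 and 5
    w = np.full(N_REGIONS, 0.0)
    w[[1, 4]] = 0.30          # labels 2 and 5
    w[[0, 2, 3, 5]] = 0.05    # rest of the lower supratentorial band
    w[6:12] = 0.025           # upper band
    w[12:] = 0.0125           # infratentorial
    return ClassParams(
        lesion_count_mean=3.0,
        lesion_count_dispersion=2.0,
        radius_mean_mm=4.5,
        radius_sd_mm=1.0,
        placement_weights=tuple(w),
        intensity_offset=30.0,
        noise_sd=12.0,
        correlation_length_mm=2.0,
        intensity_skew=0.8,
    )


def _default_as_params() -> ClassParams:
    # single unilateral frontal-like mass: upper-band sector 7 dominates
    w = np.full(N_REGIONS, 0.2 / 14.0)
    w[6] = 0.55               # label 7
    w[0] = 0.25               # label 1 (same hemisphere, lower band)
    w = w / w.sum()
    return ClassParams(
        lesion_count_mean=1.0,
        lesion_count_dispersion=0.0,
        radius_mean_mm=9.0,
        radius_sd_mm=1.5,
        placement_weights=tuple(w),
        intensity_offset=30.0,
        noise_sd=8.0,
        correlation_length_mm=5.0,
        intensity_skew=0.0,
        min_radius_mm=5.0,
    )


@dataclass
class PhantomConfig:
    """Geometry, atlas layout and per-class lesion statistics."""

    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_regions_supra: int = 12
    n_regions_infra: int = 4
    class_params: dict = field(default_factory=lambda: {})
    background_mean: float = 100.0
    background_noise_sd: float = 5.0
    scanner_bias: float = 0.0  # optional additive intensity shift per scanner index
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions_supra + self.n_regions_infra != N_REGIONS:
            raise ValueError(
                f"n_regions_supra + n_regions_infra must equal {N_REGIONS}"
            )
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("all voxel spacings must be positive")
        if not self.class_params:
            self.class_params = {"AE": _default_ae_params(), "AS": _default_as_params()}

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_spacing))

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1, default=list))


@dataclass
class PhantomSubject:
    """One simulated scan: intensities, lesion mask, atlas and metadata."""

    image: np.ndarray
    mask: np.ndarray
    atlas: np.ndarray
    class_label: str
    scanner_id: str = "scanner_0"
    seed: int = 0
    subject_id: str = "subject"


def make_atlas(config: PhantomConfig) -> np.ndarray:
    """Deterministic 16-region parcellation of an ellipsoidal brain.

    Foreground: an ellipsoid spanning ~80% of the grid.  The ventral 30%
    (last axis) is the infratentorial band, split into ``n_regions_infra``
    angular sectors (labels 13..16 by default); the rest is split into two
    axial bands x ``n_regions_supra / 2`` angular sectors (labels 1..12).
    Raises if any region ends up empty (grid too small to host 16 regions).
    """
    shape = config.grid_shape
    idx = np.indices(shape).astype(float)
    centre = (np.asarray(shape, dtype=float) - 1) / 2.0
    semi = np.asarray(shape, dtype=float) * 0.40
    u = [(idx[i] - centre[i]) / semi[i] for i in range(3)]
    brain = u[0] ** 2 + u[1] ** 2 + u[2] ** 2 <= 1.0

    z = idx[2] - centre[2]
    z_min = -semi[2]
    infra = z < z_min + 0.30 * (2 * semi[2])  # ventral 30% band
    theta = np.arctan2(u[1], u[0])  # in-plane angle, [-pi, pi)

    atlas = np.zeros(shape, dtype=np.int16)
    n_sup = config.n_regions_supra
    n_inf = config.n_regions_infra
    n_ang = max(1, n_sup // 2)
    # supratentorial: two z-bands (lower band first) x n_ang angular sectors
    sup = brain & ~infra
    z_mid = np.median(z[sup]) if sup.any() else 0.0
    sector = np.floor((theta + np.pi) / (2 * np.pi) * n_ang).astype(int)
    sector = np.clip(sector, 0, n_ang - 1)
    lower = sup & (z <= z_mid)
    upper = sup & (z > z_mid)
    atlas[lower] = sector[lower] + 1
    atlas[upper] = sector[upper] + 1 + n_ang
    if n_sup % 2:  # odd supratentorial count: last label is the top cap
        cap = upper & (z > np.percentile(z[upper], 90)) if upper.any() else upper
        atlas[cap] = n_sup
    # infratentorial: n_inf angular sectors, labels n_sup+1 .. 16
    sector_inf = np.floor((theta + np.pi) / (2 * np.pi) * n_inf).astype(int)
    sector_inf = np.clip(sector_inf, 0, n_inf - 1)
    atlas[brain & infra] = sector_inf[brain & infra] + n_sup + 1

    for label in range(1, N_REGIONS + 1):
        if not (atlas == label).any():
            raise ValueError(
                f"grid {shape} too small to host {N_REGIONS} regions: "
                f"region {label} is empty"
            )
    return atlas


def _draw_count(params: ClassParams, rng: np.random.Generator) -> int:
    m = params.lesion_count_mean
    disp = params.lesion_count_dispersion
    if disp <= 0:
        return max(1, int(round(m)))
    # negative binomial with mean m, size disp
    p = disp / (disp + m)
    return max(1, int(rng.negative_binomial(disp, p)))


def _correlated_field(
    shape, spacing, corr_len_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance smoothed Gaussian noise with physical correlation length."""
    white = rng.standard_normal(shape)
    sigma = [max(corr_len_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _grow_lesion(
    atlas: np.ndarray,
    region: int,
    radius_mm: float,
    config: PhantomConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One blob mask: irregular thresholded surface around a region voxel."""
    brain = atlas > 0
    region_voxels = np.argwhere(atlas == region)
    centre = region_voxels[rng.integers(len(region_voxels))]
    spacing = np.asarray(config.voxel_spacing)
    idx = np.indices(config.grid_shape).astype(float)
    dist = np.sqrt(
        sum(((idx[i] - centre[i]) * spacing[i]) ** 2 for i in range(3))
    )
    # irregular boundary: modulate the radius with smooth noise
    bump = _correlated_field(config.grid_shape, spacing, 2.0 * radius_mm, rng)
    blob = (dist <= radius_mm * (1.0 + 0.30 * bump)) & brain
    min_voxels = int(np.ceil(8.0 / config.voxel_volume)) + 1
    # keep only the component containing (or nearest to) the centre
    lab, nlab = ndimage.label(blob, structure=np.ones((3, 3, 3)))
    if nlab > 1:
        blob = lab == lab[tuple(centre)] if lab[tuple(centre)] else blob
    if blob.sum() < min_voxels:
        # guarantee the >= 8 mm^3 invariant: take the nearest brain voxels
        flat = np.argsort(dist[brain])[:min_voxels]
        blob = np.zeros_like(brain)
        brain_idx = np.argwhere(brain)
        blob[tuple(brain_idx[flat].T)] = True
    return blob


def simulate_subject(
    config: PhantomConfig,
    class_label: str,
    seed: int,
    atlas: np.ndarray | None = None,
    scanner_id: str = "scanner_0",
    subject_id: str = "subject",
) -> PhantomSubject:
    """Simulate one phantom scan; bit-identical for identical arguments."""
    if class_label not in config.class_params:
        raise KeyError(f"unknown class {class_label!r}; have {list(config.class_params)}")
    params = config.class_params[class_label]
    if atlas is None:
        atlas = make_atlas(config)
    rng = np.random.default_rng(seed)
    brain = atlas > 0
    spacing = config.voxel_spacing

    mask = np.zeros(config.grid_shape, dtype=bool)
    n_lesions = _draw_count(params, rng)
    weights = np.asarray(params.placement_weights)
    for _ in range(n_lesions):
        region = int(rng.choice(N_REGIONS, p=weights)) + 1
        radius = float(
            np.clip(
                rng.normal(params.radius_mean_mm, params.radius_sd_mm),
                params.min_radius_mm,
                None,
            )
        )
        mask |= _grow_lesion(atlas, region, radius, config, rng)

    image = np.zeros(config.grid_shape, dtype=float)
    image[brain] = config.background_mean + rng.normal(
        0.0, config.background_noise_sd, int(brain.sum())
    )
    if config.scanner_bias:
        try:
            scanner_index = int(str(scanner_id).rsplit("_", 1)[-1])
        except ValueError:
            scanner_index = 0
        image[brain] += config.scanner_bias * scanner_index
    texture = _correlated_field(
        config.grid_shape, spacing, params.correlation_length_mm, rng
    )
    shaped = texture + params.intensity_skew * (texture**2 - 1.0)
    image[mask] += params.intensity_offset + params.noise_sd * shaped[mask]

    return PhantomSubject(
        image=image,
        mask=mask,
        atlas=atlas,
        class_label=class_label,
        scanner_id=scanner_id,
        seed=seed,
        subject_id=subject_id,
    )


def simulate_cohort(
    config: PhantomConfig,
    n_ae: int,
    n_as: int,
    scanner_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[PhantomSubject], pd.DataFrame]:
    """Simulate a cohort of AE-like and AS-like phantoms plus a truth table.

    Per-subject seeds derive deterministically from the cohort seed; scanner
    ids are drawn from ``scanner_mix`` (default: a single scanner).
    """
    if n_ae < 0 or n_as < 0:
        raise ValueError("cohort sizes must be non-negative")
    scanner_mix = scanner_mix or {"scanner_0": 1.0}
    names = sorted(scanner_mix)
    probs = np.array([scanner_mix[s] for s in names], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    total = n_ae + n_as
    if total == 0:
        return [], pd.DataFrame(columns=["subject_id", "class", "scanner_id", "seed"])
    subject_seeds = rng.integers(0, 2**31 - 1, size=total)
    scanners = rng.choice(names, size=total, p=probs)
    atlas = make_atlas(config)
    subjects, rows = [], []
    labels = ["AE"] * n_ae + ["AS"] * n_as
    for i, label in enumerate(labels):
        sid = f"{label.lower()}_{i:04d}"
        subj = simulate_subject(
            config,
            label,
            int(subject_seeds[i]),
            atlas=atlas,
            scanner_id=str(scanners[i]),
            subject_id=sid,
        )
        subjects.append(subj)
        rows.append(
            {
                "subject_id": sid,
                "class": label,
                "scanner_id": str(scanners[i]),
                "seed": int(subject_seeds[i]),
            }
        )
    return subjects, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI input/output
# ---------------------------------------------------------------------------

def write_subject(subject: PhantomSubject, config: PhantomConfig, out_dir: str | Path) -> None:
    """Write a subject's image/mask/atlas triplet as .nii.gz."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(config.voxel_spacing) + [1.0])
    sid = subject.subject_id
    nib.save(nib.Nifti1Image(subject.image.astype(np.float32), affine), out / f"{sid}_image.nii.gz")
    nib.save(nib.Nifti1Image(subject.mask.astype(np.uint8), affine), out / f"{sid}_mask.nii.gz")
    nib.save(nib.Nifti1Image(subject.atlas.astype(np.int16), affine), out / f"{sid}_atlas.nii.gz")


def write_cohort(
    subjects: list[PhantomSubject],
    truth: pd.DataFrame,
    config: PhantomConfig,
    out_dir: str | Path,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_subject(s, config, out)
    truth.to_csv(out / "truth.csv", index=False)
    config.to_json(out / "config.json")
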