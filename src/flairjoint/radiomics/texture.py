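"""Higher-order texture features: 272 values from six matrix families.

Families and aggregations (272 = 25*4 + 16*4 + 16*2 + 16*2 + 5*2 + 17*2):

* GLCM   (25 features) x {2d_avg, 25d_mrg, 3d_avg, 3d_mrg}
* GLRLM  (16)          x {2d_avg, 25d_mrg, 3d_avg, 3d_mrg}
* GLSZM  (16)          x {2d, 3d}
* GLDZM  (16)          x {2d, 3d}
* NGTDM  (5)           x {2d, 3d}
* NGLDM  (17)          x {2d, 3d}

All matrices are built from a discretized grey-level grid (0 outside the
mask, 1..Ng inside).  3-D neighbourhoods use the 13-direction unit-offset
set at distance 1; 2-D variants operate slice-by-slice in the acquisition
plane (configurable axis, default the last) with the 4-direction in-plane
set.  GLCMs are symmetric.

Aggregation semantics: ``*_avg`` computes features per unit (slice x
direction, or direction) and averages them; ``*_mrg`` merges the count
matrices first and computes features once.  Units that contain no pairs,
runs or zones (for example a slice whose mask is a single voxel) are skipped;
if no unit yields a matrix the family's features fall back to 0.0 — the
documented degenerate value, never NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

DIRECTIONS_2D: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

GLCM_FEATURES = [
    "joint_maximum",
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "angular_second_moment",
    "contrast",
    "dissimilarity",
    "inverse_difference",
    "inverse_difference_normalised",
    "inverse_difference_moment",
    "inverse_difference_moment_normalised",
    "inverse_variance",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "information_correlation_1",
    "information_correlation_2",
]

# Shared run/zone formula template; {u} is the family's second axis:
# run length, zone size or zone distance.
_RUN_TEMPLATE = [
    "short_{u}_emphasis",
    "long_{u}_emphasis",
    "low_grey_level_emphasis",
    "high_grey_level_emphasis",
    "short_{u}_low_grey_level_emphasis",
    "short_{u}_high_grey_level_emphasis",
    "long_{u}_low_grey_level_emphasis",
    "long_{u}_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "{u}_non_uniformity",
    "{u}_non_uniformity_normalised",
    "{u}_percentage",
    "grey_level_variance",
    "{u}_variance",
    "{u}_entropy",
]

GLRLM_FEATURES = [f.format(u="run_length") for f in _RUN_TEMPLATE]
GLSZM_FEATURES = [f.format(u="zone_size") for f in _RUN_TEMPLATE]
GLDZM_FEATURES = [f.format(u="zone_distance") for f in _RUN_TEMPLATE]

NGTDM_FEATURES = ["coarseness", "contrast", "busyness", "complexity", "strength"]

NGLDM_FEATURES = [
    "low_dependence_emphasis",
    "high_dependence_emphasis",
    "low_grey_level_count_emphasis",
    "high_grey_level_count_emphasis",
    "low_dependence_low_grey_level_emphasis",
    "low_dependence_high_grey_level_emphasis",
    "high_dependence_low_grey_level_emphasis",
    "high_dependence_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "dependence_count_non_uniformity",
    "dependence_count_non_uniformity_normalised",
    "dependence_count_percentage",
    "grey_level_variance",
    "dependence_count_variance",
    "dependence_count_entropy",
    "dependence_count_energy",
]

AGGREGATIONS_DIRECTIONAL = ("2d_avg", "25d_mrg", "3d_avg", "3d_mrg")
AGGREGATIONS_ZONAL = ("2d", "3d")


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------

def _offset_slices(shape, offset):
    """Pair of slice tuples selecting voxels v and v+offset inside the grid."""
    src, dst = [], []
    for size, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, size - o))
            dst.append(slice(o, size))
        else:
            src.append(slice(-o, size))
            dst.append(slice(0, size + o))
    return tuple(src), tuple(dst)


def glcm_matrix(levels: np.ndarray, ng: int, direction) -> np.ndarray:
    """Symmetric grey-level co-occurrence counts for one offset."""
    src, dst = _offset_slices(levels.shape, direction)
    a = levels[src].ravel()
    b = levels[dst].ravel()
    keep = (a > 0) & (b > 0)
    a, b = a[keep], b[keep]
    counts = np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng).reshape(ng, ng)
    return (counts + counts.T).astype(float)


def _runs(levels: np.ndarray, direction) -> np.ndarray:
    """All maximal runs along ``direction``: array of (level, length) rows.

    Voxels are grouped into lattice lines via the invariant key
    ``k*v - d*T`` with ``T = d . v`` and ``k = |d|^2``; consecutive voxels on
    a line differ in T by exactly k.
    """
    d = np.asarray(direction)
    coords = np.indices(levels.shape).reshape(levels.ndim, -1)
    vals = levels.ravel()
    k = int((d**2).sum())
    t = (d @ coords).astype(np.int64)
    key = coords * k - d[:, None] * t
    order = np.lexsort((t, *key[::-1]))
    t_s = t[order]
    key_s = key[:, order]
    v_s = vals[order]
    same_line = (np.diff(key_s, axis=1) == 0).all(axis=0)
    contiguous = np.diff(t_s) == k
    same_run = same_line & contiguous & (np.diff(v_s) == 0)
    breaks = np.flatnonzero(~same_run)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [v_s.size - 1]))
    lengths = ends - starts + 1
    run_levels = v_s[starts]
    keep = run_levels > 0
    return np.column_stack([run_levels[keep], lengths[keep]])


def glrlm_matrix(levels: np.ndarray, ng: int, direction) -> np.ndarray:
    """Grey-level run-length counts R[g, r] for one direction."""
    runs = _runs(levels, direction)
    if runs.size == 0:
        return np.zeros((ng, 1))
    max_len = int(runs[:, 1].max())
    mat = np.zeros((ng, max_len))
    np.add.at(mat, (runs[:, 0] - 1, runs[:, 1] - 1), 1.0)
    return mat


def glszm_matrix(levels: np.ndarray, ng: int) -> np.ndarray:
    """Grey-level size-zone counts S[g, s]; zones are fully connected
    components (26-connectivity in 3-D, 8 in 2-D) of equal grey level."""
    structure = np.ones((3,) * levels.ndim, dtype=int)
    entries: list[tuple[int, int]] = []
    for g in np.unique(levels[levels > 0]):
        lab, nlab = ndimage.label(levels == g, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        entries.extend((int(g), int(s)) for s in sizes)
    if not entries:
        return np.zeros((ng, 1))
    arr = np.asarray(entries)
    mat = np.zeros((ng, int(arr[:, 1].max())))
    np.add.at(mat, (arr[:, 0] - 1, arr[:, 1] - 1), 1.0)
    return mat


def gldzm_matrix(levels: np.ndarray, ng: int) -> np.ndarray:
    """Grey-level distance-zone counts D[g, d]; a zone's distance is the
    minimum city-block distance of its voxels to outside the mask (border
    voxels have distance 1)."""
    mask = levels > 0
    # pad so voxels on the grid edge are border voxels (distance 1)
    dist = ndimage.distance_transform_cdt(np.pad(mask, 1), metric="taxicab")[
        (slice(1, -1),) * levels.ndim
    ]
    structure = np.ones((3,) * levels.ndim, dtype=int)
    entries: list[tuple[int, int]] = []
    for g in np.unique(levels[levels > 0]):
        lab, nlab = ndimage.label(levels == g, structure=structure)
        if nlab == 0:
            continue
        mins = ndimage.minimum(dist, labels=lab, index=np.arange(1, nlab + 1))
        entries.extend((int(g), int(d)) for d in np.atleast_1d(mins))
    if not entries:
        return np.zeros((ng, 1))
    arr = np.asarray(entries)
    mat = np.zeros((ng, int(arr[:, 1].max())))
    np.add.at(mat, (arr[:, 0] - 1, arr[:, 1] - 1), 1.0)
    return mat


def _neighbour_offsets(ndim: int):
    offs = np.indices((3,) * ndim).reshape(ndim, -1).T - 1
    return [tuple(o) for o in offs if any(o)]


def ngtdm_table(levels: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    """Neighbourhood grey-tone difference table: (n_g counts, s_g sums).

    Each masked voxel contributes |g - mean(level of in-mask neighbours)|;
    voxels without in-mask neighbours are excluded.
    """
    mask = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=float)
    for off in _neighbour_offsets(levels.ndim):
        src, dst = _offset_slices(levels.shape, off)
        nb_sum[dst] += np.where(mask[src], levels[src], 0)
        nb_cnt[dst] += mask[src]
    valid = mask & (nb_cnt > 0)
    diff = np.abs(levels - np.divide(nb_sum, nb_cnt, out=np.zeros_like(nb_sum), where=nb_cnt > 0))
    n_g = np.zeros(ng)
    s_g = np.zeros(ng)
    g_valid = levels[valid]
    np.add.at(n_g, g_valid - 1, 1.0)
    np.add.at(s_g, g_valid - 1, diff[valid])
    return n_g, s_g


def ngldm_matrix(levels: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Neighbouring grey-level dependence counts s[g, j].

    j - 1 is the number of Chebyshev-distance-1 in-mask neighbours whose
    level differs from the centre by at most ``alpha``.
    """
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in _neighbour_offsets(levels.ndim):
        src, dst = _offset_slices(levels.shape, off)
        dep[dst] += (mask[src] & mask[dst] & (np.abs(levels[src] - levels[dst]) <= alpha))
    g = levels[mask]
    j = dep[mask] + 1
    mat = np.zeros((ng, int(j.max())))
    np.add.at(mat, (g - 1, j - 1), 1.0)
    return mat


# ---------------------------------------------------------------------------
# feature formulas
# ---------------------------------------------------------------------------

def _safe_log2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = np.log2(p[nz])
    return out


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    """The 25 co-occurrence features from a (symmetric) count matrix."""
    total = counts.sum()
    if total == 0:
        return {k: 0.0 for k in GLCM_FEATURES}
    p = counts / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((ii * p).sum())  # symmetric: row mean == joint average
    # diagonal distributions
    kd = np.arange(ng)  # |i-j| = 0..ng-1
    p_d = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=ng)[:ng]
    ks = np.arange(2, 2 * ng + 1)
    p_s = np.bincount((ii + jj).ravel(), weights=p.ravel())[2 : 2 * ng + 1]
    d_avg = float((kd * p_d).sum())
    s_avg = float((ks * p_s).sum())
    sigma2 = float(((ii - mu) ** 2 * p).sum())
    sigma = np.sqrt(sigma2)
    hxy = float(-(p * _safe_log2(p)).sum())
    pxpy = px[:, None] * px[None, :]
    hxy1 = float(-(p * _safe_log2(pxpy)).sum())
    hxy2 = float(-(pxpy * _safe_log2(pxpy)).sum())
    hx = float(-(px * _safe_log2(px)).sum())
    if sigma2 > 0:
        corr = float(((ii * jj * p).sum() - mu**2) / sigma2)
    else:
        corr = 1.0
    inv_var_mask = ii != jj
    icm1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    icm2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return {
        "joint_maximum": float(p.max()),
        "joint_average": mu,
        "joint_variance": sigma2,
        "joint_entropy": hxy,
        "difference_average": d_avg,
        "difference_variance": float(((kd - d_avg) ** 2 * p_d).sum()),
        "difference_entropy": float(-(p_d * _safe_log2(p_d)).sum()),
        "sum_average": s_avg,
        "sum_variance": float(((ks - s_avg) ** 2 * p_s).sum()),
        "sum_entropy": float(-(p_s * _safe_log2(p_s)).sum()),
        "angular_second_moment": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "inverse_difference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "inverse_difference_normalised": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "inverse_difference_moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "inverse_difference_moment_normalised": float(
            (p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()
        ),
        "inverse_variance": float((p[inv_var_mask] / (ii - jj)[inv_var_mask] ** 2).sum()),
        "correlation": corr,
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "information_correlation_1": float(icm1),
        "information_correlation_2": icm2,
    }


def _run_type_features(mat: np.ndarray, n_voxels: int, names: list[str]) -> dict[str, float]:
    """Shared formula set for run-length, size-zone and distance-zone
    matrices: ``mat[g-1, u-1]`` counts units of grey level g and extent u."""
    ns = mat.sum()
    if ns == 0 or n_voxels == 0:
        return {k: 0.0 for k in names}
    ng, nu = mat.shape
    g = np.arange(1, ng + 1, dtype=float)
    u = np.arange(1, nu + 1, dtype=float)
    gg, uu = np.meshgrid(g, u, indexing="ij")
    p = mat / ns
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    pg = row / ns
    pu = col / ns
    mu_g = float((g * pg).sum())
    mu_u = float((u * pu).sum())
    vals = [
        float((mat / uu**2).sum() / ns),
        float((mat * uu**2).sum() / ns),
        float((mat / gg**2).sum() / ns),
        float((mat * gg**2).sum() / ns),
        float((mat / (gg**2 * uu**2)).sum() / ns),
        float((mat * gg**2 / uu**2).sum() / ns),
        float((mat * uu**2 / gg**2).sum() / ns),
        float((mat * gg**2 * uu**2).sum() / ns),
        float((row**2).sum() / ns),
        float((row**2).sum() / ns**2),
        float((col**2).sum() / ns),
        float((col**2).sum() / ns**2),
        float(ns / n_voxels),
        float(((g - mu_g) ** 2 * pg).sum()),
        float(((u - mu_u) ** 2 * pu).sum()),
        float(-(p * _safe_log2(p)).sum()),
    ]
    return dict(zip(names, vals))


def glrlm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _run_type_features(mat, n_voxels, GLRLM_FEATURES)


def glszm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _run_type_features(mat, n_voxels, GLSZM_FEATURES)


def gldzm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _run_type_features(mat, n_voxels, GLDZM_FEATURES)


def ngtdm_features(n_g: np.ndarray, s_g: np.ndarray) -> dict[str, float]:
    nv = n_g.sum()
    if nv == 0:
        return {k: 0.0 for k in NGTDM_FEATURES}
    p = n_g / nv
    g = np.arange(1, len(n_g) + 1, dtype=float)
    nz = p > 0
    ngp = int(nz.sum())
    coarse_den = float((p * s_g).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1:
        gi, gj = np.meshgrid(g[nz], g[nz], indexing="ij")
        pi, pj = np.meshgrid(p[nz], p[nz], indexing="ij")
        si, sj = np.meshgrid(s_g[nz], s_g[nz], indexing="ij")
        contrast = float((pi * pj * (gi - gj) ** 2).sum() / (ngp * (ngp - 1))) * float(
            s_g.sum() / nv
        )
        busy_den = float(np.abs(gi * pi - gj * pj).sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        complexity = float(
            (np.abs(gi - gj) * (pi * si + pj * sj) / (pi + pj)).sum() / nv
        )
        s_sum = float(s_g.sum())
        strength = float(((pi + pj) * (gi - gj) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def ngldm_features(mat: np.ndarray) -> dict[str, float]:
    ns = mat.sum()
    if ns == 0:
        return {k: 0.0 for k in NGLDM_FEATURES}
    ng, nj = mat.shape
    g = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nj + 1, dtype=float)
    gg, jj = np.meshgrid(g, j, indexing="ij")
    p = mat / ns
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    pg = row / ns
    pj = col / ns
    mu_g = float((g * pg).sum())
    mu_j = float((j * pj).sum())
    return dict(
        zip(
            NGLDM_FEATURES,
            [
                float((mat / jj**2).sum() / ns),
                float((mat * jj**2).sum() / ns),
                float((mat / gg**2).sum() / ns),
                float((mat * gg**2).sum() / ns),
                float((mat / (gg**2 * jj**2)).sum() / ns),
                float((mat * gg**2 / jj**2).sum() / ns),
                float((mat * jj**2 / gg**2).sum() / ns),
                float((mat * gg**2 * jj**2).sum() / ns),
                float((row**2).sum() / ns),
                float((row**2).sum() / ns**2),
                float((col**2).sum() / ns),
                float((col**2).sum() / ns**2),
                1.0,  # every masked voxel has a dependence count
                float(((g - mu_g) ** 2 * pg).sum()),
                float(((j - mu_j) ** 2 * pj).sum()),
                float(-(p * _safe_log2(p)).sum()),
                float((p**2).sum()),
            ],
        )
    )


# ---------------------------------------------------------------------------
# aggregation machinery
# ---------------------------------------------------------------------------

def _avg_feature_dicts(dicts: list[dict[str, float]], names: list[str]) -> dict[str, float]:
    if not dicts:
        return {k: 0.0 for k in names}
    return {k: float(np.mean([d[k] for d in dicts])) for k in names}


def _merge_matrices(mats: list[np.ndarray], ng: int) -> np.ndarray:
    if not mats:
        return np.zeros((ng, 1))
    width = max(m.shape[1] for m in mats)
    out = np.zeros((ng, width))
    for m in mats:
        out[:, : m.shape[1]] += m
    return out


def _slices(levels: np.ndarray, axis: int):
    for idx in range(levels.shape[axis]):
        sl = np.take(levels, idx, axis=axis)
        if (sl > 0).any():
            yield sl


def texture_features(
    levels: np.ndarray, ng: int, slice_axis: int = 2
) -> dict[str, float]:
    """All 272 texture features of a discretized grey-level grid.

    Keys are ``{family}_{feature}_{aggregation}`` in catalog order.
    """
    out: dict[str, float] = {}
    n_voxels_3d = int((levels > 0).sum())

    # --- GLCM -------------------------------------------------------------
    per_slice_dir: list[dict[str, float]] = []
    mats_2d: list[np.ndarray] = []
    for sl in _slices(levels, slice_axis):
        for d in DIRECTIONS_2D:
            m = glcm_matrix(sl, ng, d)
            if m.sum() > 0:
                per_slice_dir.append(glcm_features(m))
                mats_2d.append(m)
    mats_3d = [glcm_matrix(levels, ng, d) for d in DIRECTIONS_3D]
    mats_3d_nz = [m for m in mats_3d if m.sum() > 0]
    agg = {
        "2d_avg": _avg_feature_dicts(per_slice_dir, GLCM_FEATURES),
        "25d_mrg": glcm_features(_merge_matrices(mats_2d, ng))
        if mats_2d
        else {k: 0.0 for k in GLCM_FEATURES},
        "3d_avg": _avg_feature_dicts([glcm_features(m) for m in mats_3d_nz], GLCM_FEATURES),
        "3d_mrg": glcm_features(_merge_matrices(mats_3d_nz, ng))
        if mats_3d_nz
        else {k: 0.0 for k in GLCM_FEATURES},
    }
    for a in AGGREGATIONS_DIRECTIONAL:
        for k in GLCM_FEATURES:
            out[f"glcm_{k}_{a}"] = agg[a][k]

    # --- GLRLM ------------------------------------------------------------
    per_slice_dir = []
    mats_2d = []
    slice_voxels: list[int] = []
    for sl in _slices(levels, slice_axis):
        nv = int((sl > 0).sum())
        for d in DIRECTIONS_2D:
            m = glrlm_matrix(sl, ng, d)
            if m.sum() > 0:
                per_slice_dir.append(glrlm_features(m, nv))
                mats_2d.append(m)
                slice_voxels.append(nv)
    rl_3d = [glrlm_matrix(levels, ng, d) for d in DIRECTIONS_3D]
    rl_3d_nz = [m for m in rl_3d if m.sum() > 0]
    # merged 2.5D voxel basis: each (slice, direction) unit contributes its
    # slice's voxels once
    agg = {
        "2d_avg": _avg_feature_dicts(per_slice_dir, GLRLM_FEATURES),
        "25d_mrg": glrlm_features(_merge_matrices(mats_2d, ng), int(np.sum(slice_voxels)))
        if mats_2d
        else {k: 0.0 for k in GLRLM_FEATURES},
        "3d_avg": _avg_feature_dicts(
            [glrlm_features(m, n_voxels_3d) for m in rl_3d_nz], GLRLM_FEATURES
        ),
        "3d_mrg": glrlm_features(
            _merge_matrices(rl_3d_nz, ng), n_voxels_3d * len(rl_3d_nz)
        )
        if rl_3d_nz
        else {k: 0.0 for k in GLRLM_FEATURES},
    }
    for a in AGGREGATIONS_DIRECTIONAL:
        for k in GLRLM_FEATURES:
            out[f"glrlm_{k}_{a}"] = agg[a][k]

    # --- zonal families ---------------------------------------------------
    def zonal(build, feats, names, family, needs_voxels=True):
        dicts = []
        for sl in _slices(levels, slice_axis):
            nv = int((sl > 0).sum())
            m = build(sl)
            if (m.sum() if isinstance(m, np.ndarray) else m[0].sum()) > 0:
                dicts.append(feats(m, nv) if needs_voxels else feats(*m))
        out2d = _avg_feature_dicts(dicts, names)
        m3 = build(levels)
        has3 = (m3.sum() if isinstance(m3, np.ndarray) else m3[0].sum()) > 0
        out3d = (
            (feats(m3, n_voxels_3d) if needs_voxels else feats(*m3))
            if has3
            else {k: 0.0 for k in names}
        )
        for k in names:
            out[f"{family}_{k}_2d"] = out2d[k]
        for k in names:
            out[f"{family}_{k}_3d"] = out3d[k]

    zonal(lambda lv: glszm_matrix(lv, ng), glszm_features, GLSZM_FEATURES, "glszm")
    zonal(lambda lv: gldzm_matrix(lv, ng), gldzm_features, GLDZM_FEATURES, "gldzm")
    zonal(
        lambda lv: ngtdm_table(lv, ng),
        ngtdm_features,
        NGTDM_FEATURES,
        "ngtdm",
        needs_voxels=False,
    )
    zonal(
        lambda lv: (ngldm_matrix(lv, ng),),
        lambda m: ngldm_features(m),
        NGLDM_FEATURES,
        "ngldm",
        needs_voxels=False,
    )
    return out
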