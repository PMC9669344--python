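"""Morphology family: 29 shape and density features of the lesion mask.

Mesh-based quantities use a marching-cubes surface of the binary mask at the
0.5 iso-level.  Axis lengths derive from the principal components of the
voxel-centre point cloud.  The oriented-bounding-box and minimum-enclosing-
ellipsoid densities use standard approximations: a PCA-oriented box, and the
Khachiyan minimum-volume enclosing ellipsoid of the convex-hull vertices.

Single-voxel masks (no interior for marching cubes) fall back to treating the
voxel as a box: its surface and volume are the voxel's own.  No feature ever
returns a non-finite value.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .lesion import LesionImage

MORPHOLOGY_FEATURES = [
    "morph_volume_mesh",
    "morph_volume_voxel",
    "morph_surface_area",
    "morph_surface_to_volume_ratio",
    "morph_compactness_1",
    "morph_compactness_2",
    "morph_spherical_disproportion",
    "morph_sphericity",
    "morph_asphericity",
    "morph_centre_of_mass_shift",
    "morph_max_3d_diameter",
    "morph_major_axis_length",
    "morph_minor_axis_length",
    "morph_least_axis_length",
    "morph_elongation",
    "morph_flatness",
    "morph_volume_density_aabb",
    "morph_area_density_aabb",
    "morph_volume_density_ombb",
    "morph_area_density_ombb",
    "morph_volume_density_aee",
    "morph_area_density_aee",
    "morph_volume_density_mvee",
    "morph_area_density_mvee",
    "morph_volume_density_convex_hull",
    "morph_area_density_convex_hull",
    "morph_integrated_intensity",
    "morph_morans_i",
    "morph_gearys_c",
]

# Deterministic subsample cap for the O(n^2) autocorrelation features.
_AUTOCORR_MAX_VOXELS = 1500


def _mesh(mask: np.ndarray, spacing: tuple[float, float, float]):
    """Marching-cubes mesh (vertices in mm) of the padded mask.

    The binary field is lightly smoothed before meshing: the raw 0/1 field
    yields a staircase surface whose area overestimates a smooth boundary by
    ~8%, which would bias sphericity/compactness for every lesion.  If
    smoothing erodes the lesion below the iso-level (very small masks) the
    raw field is meshed instead.
    """
    from scipy import ndimage as _ndi

    padded = np.pad(mask.astype(float), 2)
    smoothed = _ndi.gaussian_filter(padded, sigma=0.6)
    field = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=spacing)
    verts = verts - 2 * np.asarray(spacing)  # undo padding offset
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    """Signed tetrahedron sum (divergence theorem)."""
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    """Thomsen's approximation of an ellipsoid's surface area."""
    p = 1.6075
    if min(a, b, c) <= 0:
        return 0.0
    s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return float(4.0 * np.pi * s ** (1.0 / p))


def _mvee(points: np.ndarray, tol: float = 1e-3) -> np.ndarray:
    """Semi-axis lengths of the minimum-volume enclosing ellipsoid.

    Khachiyan's algorithm on the (few) convex-hull vertices; tolerance is
    loose because the feature is a density ratio, not a geometric primitive.
    """
    pts = np.unique(points, axis=0)
    # centre the cloud for numerical stability (MVEE is translation-equivariant)
    shift = pts.mean(axis=0)
    pts = pts - shift
    n, d = pts.shape
    if n <= d:  # degenerate cloud: fall back to half the extent
        ext = pts.max(axis=0) - pts.min(axis=0)
        return np.maximum(ext / 2.0, 1e-9)
    q = np.vstack([pts.T, np.ones(n)])  # (d+1, n)
    u = np.full(n, 1.0 / n)
    for _ in range(500):
        x = (q * u) @ q.T
        m = np.einsum("ij,ij->j", q, np.linalg.solve(x, q))
        j = int(np.argmax(m))
        eps = m[j] - (d + 1.0)
        if eps <= tol * (d + 1.0):
            break
        step = eps / ((d + 1.0) * (m[j] - 1.0))
        u *= 1.0 - step
        u[j] += step
    centre = pts.T @ u
    cov = ((pts * u[:, None]).T @ pts - np.outer(centre, centre)) / d
    eigvals = np.linalg.eigvalsh(cov)
    return np.sqrt(np.maximum(eigvals, 1e-18))[::-1]


def _autocorrelation(coords: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Moran's I and Geary's C with inverse-distance weights.

    Exact for small lesions; larger lesions use a fixed-seed subsample so the
    result stays deterministic.
    """
    n = coords.shape[0]
    if n < 2 or x.var() == 0:
        return 1.0, 0.0  # degenerate convention: perfect self-similarity
    if n > _AUTOCORR_MAX_VOXELS:
        idx = np.random.default_rng(0).choice(n, _AUTOCORR_MAX_VOXELS, replace=False)
        idx.sort()
        coords, x = coords[idx], x[idx]
        n = _AUTOCORR_MAX_VOXELS
    mean = x.mean()
    dev = x - mean
    ss = float((dev**2).sum())
    num_i = num_c = wsum = 0.0
    for i in range(n - 1):
        d = np.linalg.norm(coords[i + 1 :] - coords[i], axis=1)
        w = 1.0 / d
        wsum += w.sum()
        num_i += float((w * dev[i] * dev[i + 1 :]).sum())
        num_c += float((w * (x[i] - x[i + 1 :]) ** 2).sum())
    # Sums above cover each unordered pair once; symmetric weights double them.
    morans = (n / (2 * wsum)) * (2 * num_i) / ss
    gearys = ((n - 1) / (2 * (2 * wsum))) * (2 * num_c) / ss
    return float(morans), float(gearys)


def morphology_features(lesion: LesionImage) -> dict[str, float]:
    """Compute the 29 morphology features for one lesion."""
    mask = lesion.mask
    spacing = np.asarray(lesion.spacing)
    voxvol = lesion.voxel_volume
    n_vox = lesion.n_voxels
    volume_voxel = n_vox * voxvol

    coords = np.argwhere(mask) * spacing  # voxel centres in mm
    intens = lesion.values

    try:
        verts, faces = _mesh(mask, lesion.spacing)
        surface_area = float(measure.mesh_surface_area(verts, faces))
        volume_mesh = _mesh_volume(verts, faces)
    except (RuntimeError, ValueError):
        # single-voxel / degenerate: voxel-as-box convention
        verts = None
        surface_area = 2.0 * (
            spacing[0] * spacing[1] + spacing[0] * spacing[2] + spacing[1] * spacing[2]
        ) * n_vox
        volume_mesh = volume_voxel
    if volume_mesh <= 0:
        volume_mesh = volume_voxel

    sphericity = (36.0 * np.pi * volume_mesh**2) ** (1.0 / 3.0) / surface_area
    compact1 = volume_mesh / (np.pi**0.5 * surface_area**1.5)
    compact2 = 36.0 * np.pi * volume_mesh**2 / surface_area**3
    asphericity = (surface_area**3 / (36.0 * np.pi * volume_mesh**2)) ** (1.0 / 3.0) - 1.0

    # PCA axes of the voxel-centre cloud (population covariance).
    if n_vox > 1:
        eigvals = np.linalg.eigvalsh(np.cov(coords.T, bias=True))
        eigvals = np.maximum(eigvals, 0.0)[::-1]
    else:
        eigvals = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()
    elongation = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 1.0
    flatness = float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else 1.0

    # Hull-based quantities use mesh vertices when available, else centres.
    cloud = verts if verts is not None else coords
    try:
        hull = ConvexHull(cloud)
        hull_pts = cloud[hull.vertices]
        hull_volume = float(hull.volume)
        hull_area = float(hull.area)
    except (QhullError, ValueError):
        hull_pts = cloud
        hull_volume = volume_voxel
        hull_area = surface_area
    diffs = hull_pts[:, None, :] - hull_pts[None, :, :]
    max_diam = float(np.sqrt((diffs**2).sum(axis=2).max())) if len(hull_pts) > 1 else 0.0

    # Axis-aligned bounding box of the mesh/point cloud.
    ext_aabb = cloud.max(axis=0) - cloud.min(axis=0)
    ext_aabb = np.maximum(ext_aabb, np.asarray(spacing) * 0)  # keep >= 0
    vol_aabb = float(np.prod(np.maximum(ext_aabb, 1e-9)))
    area_aabb = 2.0 * float(
        ext_aabb[0] * ext_aabb[1] + ext_aabb[0] * ext_aabb[2] + ext_aabb[1] * ext_aabb[2]
    )

    # Oriented bounding box: PCA-rotated frame (standard approximation).
    if n_vox > 1:
        _, eigvecs = np.linalg.eigh(np.cov(coords.T, bias=True))
        rotated = cloud @ eigvecs
        ext_ombb = rotated.max(axis=0) - rotated.min(axis=0)
    else:
        ext_ombb = ext_aabb
    vol_ombb = float(np.prod(np.maximum(ext_ombb, 1e-9)))
    area_ombb = 2.0 * float(
        ext_ombb[0] * ext_ombb[1] + ext_ombb[0] * ext_ombb[2] + ext_ombb[1] * ext_ombb[2]
    )

    # Approximate enclosing ellipsoid (PCA semi-axes) and MVEE.
    semi = 2.0 * np.sqrt(eigvals)
    vol_aee = float(4.0 / 3.0 * np.pi * np.prod(np.maximum(semi, 1e-9)))
    area_aee = _ellipsoid_area(*np.maximum(semi, 1e-9))
    mvee_semi = _mvee(hull_pts)
    vol_mvee = float(4.0 / 3.0 * np.pi * np.prod(np.maximum(mvee_semi, 1e-9)))
    area_mvee = _ellipsoid_area(*np.maximum(mvee_semi, 1e-9))

    # Centre-of-mass shift between unweighted and intensity-weighted centroids.
    com_geom = coords.mean(axis=0)
    wsum = intens.sum()
    com_int = (coords * intens[:, None]).sum(axis=0) / wsum if wsum != 0 else com_geom
    com_shift = float(np.linalg.norm(com_geom - com_int))

    integrated = float(intens.mean() * volume_voxel)
    morans, gearys = _autocorrelation(coords, intens)

    def _density(v: float) -> float:
        return volume_mesh / v if v > 0 else 1.0

    return {
        "morph_volume_mesh": volume_mesh,
        "morph_volume_voxel": volume_voxel,
        "morph_surface_area": surface_area,
        "morph_surface_to_volume_ratio": surface_area / volume_mesh,
        "morph_compactness_1": float(compact1),
        "morph_compactness_2": float(compact2),
        "morph_spherical_disproportion": float(1.0 / sphericity),
        "morph_sphericity": float(sphericity),
        "morph_asphericity": float(asphericity),
        "morph_centre_of_mass_shift": com_shift,
        "morph_max_3d_diameter": max_diam,
        "morph_major_axis_length": float(major),
        "morph_minor_axis_length": float(minor),
        "morph_least_axis_length": float(least),
        "morph_elongation": elongation,
        "morph_flatness": flatness,
        "morph_volume_density_aabb": _density(vol_aabb),
        "morph_area_density_aabb": surface_area / area_aabb if area_aabb > 0 else 1.0,
        "morph_volume_density_ombb": _density(vol_ombb),
        "morph_area_density_ombb": surface_area / area_ombb if area_ombb > 0 else 1.0,
        "morph_volume_density_aee": _density(vol_aee),
        "morph_area_density_aee": surface_area / area_aee if area_aee > 0 else 1.0,
        "morph_volume_density_mvee": _density(vol_mvee),
        "morph_area_density_mvee": surface_area / area_mvee if area_mvee > 0 else 1.0,
        "morph_volume_density_convex_hull": _density(hull_volume),
        "morph_area_density_convex_hull": surface_area / hull_area if hull_area > 0 else 1.0,
        "morph_integrated_intensity": integrated,
        "morph_morans_i": morans,
        "morph_gearys_c": gearys,
    }
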