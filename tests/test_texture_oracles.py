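"""Texture matrix builders against brute-force enumeration oracles.

The oracles walk voxels, pairs, lines and zones explicitly in Python and are
kept deliberately independent of the vectorized builders they check.
"""

import numpy as np
import pytest


from flairjoint.radiomics.texture import (
    DIRECTIONS_3D,
    glcm_features,
    glcm_matrix,
    gldzm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_matrix,
    ngldm_matrix,
    ngtdm_table,
)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_glcm(levels, ng, direction):
    """Count co-occurring level pairs voxel by voxel (symmetric)."""
    mat = np.zeros((ng, ng))
    d = np.asarray(direction)
    for idx in np.ndindex(levels.shape):
        a = levels[idx]
        if a == 0:
            continue
        nb = tuple(np.asarray(idx) + d)
        if all(0 <= n < s for n, s in zip(nb, levels.shape)):
            b = levels[nb]
            if b > 0:
                mat[a - 1, b - 1] += 1
                mat[b - 1, a - 1] += 1
    return mat


def brute_runs(levels, ng, direction):
    """Walk every lattice line voxel by voxel and record maximal runs."""
    d = np.asarray(direction)
    shape = levels.shape
    mat = {}
    starts = [
        idx
        for idx in np.ndindex(shape)
        if not all(0 <= c < s for c, s in zip(np.asarray(idx) - d, shape))
    ]
    for start in starts:
        pos = np.asarray(start)
        current, length = 0, 0
        while all(0 <= c < s for c, s in zip(pos, shape)):
            v = levels[tuple(pos)]
            if v == current:
                length += 1
            else:
                if current > 0:
                    mat[(current, length)] = mat.get((current, length), 0) + 1
                current, length = v, 1
            pos = pos + d
        if current > 0:
            mat[(current, length)] = mat.get((current, length), 0) + 1
    if not mat:
        return np.zeros((ng, 1))
    width = max(r for _, r in mat)
    out = np.zeros((ng, width))
    for (g, r), c in mat.items():
        out[g - 1, r - 1] = c
    return out


def brute_zones(levels, ng):
    """Flood-fill zones of equal level with full (26/8) connectivity."""
    shape = levels.shape
    offsets = [
        o
        for o in np.ndindex(*(3,) * levels.ndim)
        if any(c != 1 for c in o)
    ]
    offsets = [np.asarray(o) - 1 for o in offsets]
    seen = np.zeros(shape, dtype=bool)
    sizes = []
    for idx in np.ndindex(shape):
        if levels[idx] == 0 or seen[idx]:
            continue
        g = levels[idx]
        stack = [idx]
        seen[idx] = True
        count = 0
        while stack:
            cur = stack.pop()
            count += 1
            for off in offsets:
                nb = tuple(np.asarray(cur) + off)
                if (
                    all(0 <= c < s for c, s in zip(nb, shape))
                    and not seen[nb]
                    and levels[nb] == g
                ):
                    seen[nb] = True
                    stack.append(nb)
        sizes.append((g, count))
    if not sizes:
        return np.zeros((ng, 1))
    out = np.zeros((ng, max(s for _, s in sizes)))
    for g, s in sizes:
        out[g - 1, s - 1] += 1
    return out


def _random_grids(n, max_side=5, ng=3, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        shape = tuple(rng.integers(1, max_side + 1, size=3))
        levels = rng.integers(0, ng + 1, size=shape)
        if (levels > 0).sum() == 0:
            levels.flat[0] = 1
        yield levels


# ---------------------------------------------------------------------------
# oracle-equivalence tests
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(4))
def test_glcm_matches_bruteforce_on_random_grids(seed):
    """Co-occurrence counts equal explicit pair enumeration, all directions."""
    for levels in _random_grids(25, seed=seed):
        ng = max(int(levels.max()), 1)
        for d in DIRECTIONS_3D:
            fast = glcm_matrix(levels, ng, d)
            slow = brute_glcm(levels, ng, d)
            np.testing.assert_allclose(fast, slow, atol=1e-10)


@pytest.mark.parametrize("seed", range(4))
def test_glrlm_matches_line_walking_oracle(seed):
    """Run-length counts equal voxel-by-voxel line walks, all directions."""
    for levels in _random_grids(25, seed=100 + seed):
        ng = max(int(levels.max()), 1)
        for d in DIRECTIONS_3D:
            fast = glrlm_matrix(levels, ng, d)
            slow = brute_runs(levels, ng, d)
            w = max(fast.shape[1], slow.shape[1])
            fast = np.pad(fast, ((0, 0), (0, w - fast.shape[1])))
            slow = np.pad(slow, ((0, 0), (0, w - slow.shape[1])))
            np.testing.assert_allclose(fast, slow, atol=1e-10)


@pytest.mark.parametrize("seed", range(4))
def test_glszm_matches_floodfill_oracle(seed):
    """Size-zone counts equal explicit flood-fill with 26-connectivity."""
    for levels in _random_grids(25, seed=200 + seed):
        ng = max(int(levels.max()), 1)
        fast = glszm_matrix(levels, ng)
        slow = brute_zones(levels, ng)
        w = max(fast.shape[1], slow.shape[1])
        fast = np.pad(fast, ((0, 0), (0, w - fast.shape[1])))
        slow = np.pad(slow, ((0, 0), (0, w - slow.shape[1])))
        np.testing.assert_allclose(fast, slow, atol=1e-10)


def test_glcm_features_from_brute_matrix_agree():
    """Feature values computed from the fast and brute matrices coincide."""
    rng = np.random.default_rng(7)
    levels = rng.integers(1, 4, size=(4, 4, 1))
    ng = 3
    for d in DIRECTIONS_3D:
        fast = glcm_features(glcm_matrix(levels, ng, d))
        slow = glcm_features(brute_glcm(levels, ng, d))
        for k in fast:
            assert fast[k] == pytest.approx(slow[k], abs=1e-10)


def test_gldzm_distances_match_bfs_oracle():
    """Zone distances equal a breadth-first city-block distance transform."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        shape = tuple(rng.integers(2, 6, size=3))
        levels = rng.integers(0, 4, size=shape)
        if (levels > 0).sum() == 0:
            levels.flat[0] = 1
        ng = max(int(levels.max()), 1)
        mask = levels > 0
        # oracle distance: 1 + city-block steps to leave the mask
        dist = np.full(shape, np.inf)
        frontier = []
        for idx in np.ndindex(shape):
            if mask[idx]:
                on_border = False
                for ax in range(3):
                    for s in (-1, 1):
                        nb = list(idx)
                        nb[ax] += s
                        nb = tuple(nb)
                        if not all(0 <= c < n for c, n in zip(nb, shape)) or not mask[nb]:
                            on_border = True
                if on_border:
                    dist[idx] = 1.0
                    frontier.append(idx)
        while frontier:
            nxt = []
            for idx in frontier:
                for ax in range(3):
                    for s in (-1, 1):
                        nb = list(idx)
                        nb[ax] += s
                        nb = tuple(nb)
                        if (
                            all(0 <= c < n for c, n in zip(nb, shape))
                            and mask[nb]
                            and dist[nb] > dist[idx] + 1
                        ):
                            dist[nb] = dist[idx] + 1
                            nxt.append(nb)
            frontier = nxt
        # oracle matrix from brute zones + distance minima
        fast = gldzm_matrix(levels, ng)
        slow: dict[tuple[int, int], int] = {}
        seen = np.zeros(shape, dtype=bool)
        offsets = [np.asarray(o) - 1 for o in np.ndindex(3, 3, 3) if any(c != 1 for c in o)]
        for idx in np.ndindex(shape):
            if levels[idx] == 0 or seen[idx]:
                continue
            g = levels[idx]
            stack, zone = [idx], [idx]
            seen[idx] = True
            while stack:
                cur = stack.pop()
                for off in offsets:
                    nb = tuple(np.asarray(cur) + off)
                    if (
                        all(0 <= c < n for c, n in zip(nb, shape))
                        and not seen[nb]
                        and levels[nb] == g
                    ):
                        seen[nb] = True
                        stack.append(nb)
                        zone.append(nb)
            dmin = int(min(dist[z] for z in zone))
            slow[(g, dmin)] = slow.get((g, dmin), 0) + 1
        for (g, d0), c in slow.items():
            assert fast[g - 1, d0 - 1] == c
        assert fast.sum() == sum(slow.values())


def test_ngtdm_table_matches_neighbourhood_oracle():
    """n_g and s_g equal per-voxel neighbourhood averaging done explicitly."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        shape = tuple(rng.integers(2, 6, size=3))
        levels = rng.integers(0, 4, size=shape)
        if (levels > 0).sum() == 0:
            levels.flat[0] = 1
        ng = max(int(levels.max()), 1)
        n_g, s_g = ngtdm_table(levels, ng)
        n_o = np.zeros(ng)
        s_o = np.zeros(ng)
        offsets = [np.asarray(o) - 1 for o in np.ndindex(3, 3, 3) if any(c != 1 for c in o)]
        for idx in np.ndindex(shape):
            g = levels[idx]
            if g == 0:
                continue
            nbs = []
            for off in offsets:
                nb = tuple(np.asarray(idx) + off)
                if all(0 <= c < n for c, n in zip(nb, shape)) and levels[nb] > 0:
                    nbs.append(levels[nb])
            if nbs:
                n_o[g - 1] += 1
                s_o[g - 1] += abs(g - np.mean(nbs))
        np.testing.assert_allclose(n_g, n_o, atol=1e-10)
        np.testing.assert_allclose(s_g, s_o, atol=1e-10)


def test_ngldm_matrix_matches_dependence_oracle():
    """Dependence counts equal explicit Chebyshev-1 neighbour comparison."""
    rng = np.random.default_rng(13)
    for _ in range(20):
        shape = tuple(rng.integers(2, 6, size=3))
        levels = rng.integers(0, 4, size=shape)
        if (levels > 0).sum() == 0:
            levels.flat[0] = 1
        ng = max(int(levels.max()), 1)
        fast = ngldm_matrix(levels, ng)
        offsets = [np.asarray(o) - 1 for o in np.ndindex(3, 3, 3) if any(c != 1 for c in o)]
        slow: dict[tuple[int, int], int] = {}
        for idx in np.ndindex(shape):
            g = levels[idx]
            if g == 0:
                continue
            k = 0
            for off in offsets:
                nb = tuple(np.asarray(idx) + off)
                if all(0 <= c < n for c, n in zip(nb, shape)) and levels[nb] == g:
                    k += 1
            slow[(g, k + 1)] = slow.get((g, k + 1), 0) + 1
        for (g, j), c in slow.items():
            assert fast[g - 1, j - 1] == c
        assert fast.sum() == sum(slow.values())


# ---------------------------------------------------------------------------
# directed degenerate-case checks
# ---------------------------------------------------------------------------

def test_constant_image_glcm_degenerates_to_identity():
    levels = np.ones((4, 4, 4), dtype=int)
    feats = glcm_features(glcm_matrix(levels, 1, (0, 0, 1)))
    assert feats["joint_maximum"] == 1.0
    assert feats["joint_entropy"] == 0.0


def test_single_row_single_run_normalised_nonuniformity_is_one():
    levels = np.ones((1, 1, 7), dtype=int)
    mat = glrlm_matrix(levels, 1, (0, 0, 1))
    feats = glrlm_features(mat, 7)
    assert feats["run_length_non_uniformity_normalised"] == pytest.approx(1.0)
    assert mat[0, 6] == 1  # one run of length 7
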