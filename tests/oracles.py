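"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (BFS flood fill, exhaustive searches,
per-voxel enumeration) and shares no code with the package internals.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def neighbor_offsets_3d(connectivity: int):
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS connected-component labeling; labels 1..K in raster order of discovery."""
    mask = np.asarray(mask, dtype=bool)
    offs = neighbor_offsets_3d(connectivity)
    out = np.zeros(mask.shape, dtype=np.int32)
    nz, ny, nx = mask.shape
    next_label = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or out[z, y, x]:
                    continue
                next_label += 1
                queue = deque([(z, y, x)])
                out[z, y, x] = next_label
                while queue:
                    cz, cy, cx = queue.popleft()
                    for dz, dy, dx in offs:
                        pz, py, px = cz + dz, cy + dy, cx + dx
                        if 0 <= pz < nz and 0 <= py < ny and 0 <= px < nx:
                            if mask[pz, py, px] and not out[pz, py, px]:
                                out[pz, py, px] = next_label
                                queue.append((pz, py, px))
    return out


def otsu_brute_force(data: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive between-class-variance search over histogram bin centers.

    Empty histogram gaps produce plateaus of mathematically equal variance
    whose floating-point values differ in the last few ulps; ties within
    relative tolerance resolve to the lowest threshold.
    """
    data = np.asarray(data, dtype=float).ravel()
    counts, edges = np.histogram(data, bins=nbins, range=(data.min(), data.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    variances = np.full(nbins, -np.inf)
    for cut in range(1, nbins):
        w0 = counts[:cut].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:cut] * centers[:cut]).sum() / w0
        mu1 = (counts[cut:] * centers[cut:]).sum() / w1
        variances[cut] = w0 * w1 * (mu0 - mu1) ** 2
    vmax = variances.max()
    best_cut = int(np.nonzero(variances >= vmax * (1 - 1e-10))[0][0])
    return float(centers[best_cut - 1])


def exhaustive_seed_search(
    img: np.ndarray, region: np.ndarray, n: int, connectivity: int
):
    """Exhaustive sweep of every distinct region intensity.

    Returns (threshold, labeled seeds) maximizing the smallest component's
    size among thresholds giving exactly n components, ties to the lowest
    threshold; None if no threshold qualifies.
    """
    best = None
    for t in np.unique(img[region]):
        lab = flood_fill_label(region & (img >= t), connectivity)
        k = lab.max()
        if k != n:
            continue
        min_size = min(int((lab == c).sum()) for c in range(1, k + 1))
        if best is None or min_size > best[0]:
            best = (min_size, float(t), lab)
    if best is None:
        return None
    return best[1], best[2]


def grow_eligible_brute_force(
    img2d: np.ndarray, region2d: np.ndarray, sel: tuple[int, int]
) -> np.ndarray:
    """Enumerate the in-plane constrained-growth result voxel by voxel.

    A background voxel joins iff intensity >= intensity at ``sel``, Euclidean
    distance to the nearest region voxel <= that of ``sel``, and it is
    8-connected to the region through qualifying voxels.
    """
    sy, sx = sel
    ny, nx = img2d.shape
    rvox = np.argwhere(region2d)

    def dist_to_region(y, x):
        return np.sqrt(((rvox - (y, x)) ** 2).sum(axis=1)).min()

    t = img2d[sy, sx]
    d_star = dist_to_region(sy, sx)
    eligible = np.zeros_like(region2d)
    for y in range(ny):
        for x in range(nx):
            if region2d[y, x]:
                continue
            if img2d[y, x] >= t and dist_to_region(y, x) <= d_star:
                eligible[y, x] = True
    # BFS from the region through eligible voxels (8-connectivity)
    joined = np.zeros_like(region2d)
    queue = deque(map(tuple, rvox))
    seen = set(map(tuple, rvox))
    while queue:
        cy, cx = queue.popleft()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                py, px = cy + dy, cx + dx
                if (dy, dx) != (0, 0) and 0 <= py < ny and 0 <= px < nx:
                    if (py, px) not in seen and eligible[py, px]:
                        seen.add((py, px))
                        joined[py, px] = True
                        queue.append((py, px))
    return region2d | joined
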