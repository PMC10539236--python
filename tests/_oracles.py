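"""Independent brute-force oracles for the test suite.

Deliberately naive implementations — dense convolution, exhaustive search,
flood fill, all-pairs distances, explicit neighborhood morphology — kept
separate from the library code paths they validate.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np

CONNECTIVITY_OFFSETS = {
    6: [o for o in itertools.product((-1, 0, 1), repeat=3)
        if sum(abs(v) for v in o) == 1],
    18: [o for o in itertools.product((-1, 0, 1), repeat=3)
         if 1 <= sum(abs(v) for v in o) <= 2],
    26: [o for o in itertools.product((-1, 0, 1), repeat=3)
         if any(o)],
}


def sampled_gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    """Normalized 3D Gaussian sampled on [-radius, radius]^3."""
    ax = np.arange(-radius, radius + 1, dtype=float)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    k = np.exp(-(zz**2 + yy**2 + xx**2) / (2.0 * sigma**2))
    return k / k.sum()


def dense_convolve_center(impulse_volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct dense convolution, valid when the kernel support stays inside
    the volume (no boundary handling needed)."""
    out = np.zeros_like(impulse_volume, dtype=float)
    r = kernel.shape[0] // 2
    nz, ny, nx = impulse_volume.shape
    for z, y, x in zip(*np.nonzero(impulse_volume)):
        w = impulse_volume[z, y, x]
        out[z - r:z + r + 1, y - r:y + r + 1, x - r:x + r + 1] += w * kernel
    return out


def brute_otsu(data: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive search over equal-width bin edges maximising between-class
    variance computed directly from the data (classes split by >= edge)."""
    flat = np.asarray(data, dtype=float).ravel()
    edges = np.linspace(flat.min(), flat.max(), n_bins + 1)
    best_edge, best_var = None, -1.0
    for edge in edges[1:-1]:
        lo = flat[flat < edge]
        hi = flat[flat >= edge]
        if lo.size == 0 or hi.size == 0:
            continue
        var = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if var > best_var * (1 + 1e-12):
            best_var, best_edge = var, edge
    return float(best_edge)


def flood_fill_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Label components by breadth-first flood fill from every unvisited voxel."""
    offsets = CONNECTIVITY_OFFSETS[connectivity]
    labels = np.zeros(mask.shape, dtype=int)
    next_label = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        next_label += 1
        queue = deque([start])
        labels[start] = next_label
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if (0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1]
                        and 0 <= p[2] < mask.shape[2]
                        and mask[p] and not labels[p]):
                    labels[p] = next_label
                    queue.append(p)
    return labels


def brute_signed_distance(mask: np.ndarray, voxel_size_um: float) -> np.ndarray:
    """All-pairs nearest-opposite-class signed distance in um: positive on
    background (distance to nearest true voxel center), negative on true
    voxels (distance to nearest background voxel center)."""
    from scipy.spatial.distance import cdist

    true_pts = np.argwhere(mask).astype(float)
    false_pts = np.argwhere(~mask).astype(float)
    out = np.empty(mask.shape, dtype=float)
    d_bg = cdist(false_pts, true_pts).min(axis=1)
    d_fg = cdist(true_pts, false_pts).min(axis=1)
    out[~mask] = d_bg
    out[mask] = -d_fg
    return out * voxel_size_um


def ball_offsets(radius: int) -> list[tuple[int, int, int]]:
    """Integer offsets whose center distance is <= radius (Euclidean ball)."""
    r = int(radius)
    return [
        (dz, dy, dx)
        for dz in range(-r, r + 1)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dz * dz + dy * dy + dx * dx <= r * r
    ]


def brute_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Dilation then erosion by explicit neighborhood maxima/minima over the
    Euclidean ball, on a zero-padded copy (no wrap-around)."""
    r = int(radius)
    offsets = ball_offsets(r)
    padded = np.pad(mask, 2 * r)  # room for dilation to grow by r

    def dilate(m):
        out = np.zeros_like(m)
        for dz, dy, dx in offsets:
            out |= np.roll(m, (dz, dy, dx), axis=(0, 1, 2))
        return out

    def erode(m):
        out = np.ones_like(m)
        for dz, dy, dx in offsets:
            out &= np.roll(m, (dz, dy, dx), axis=(0, 1, 2))
        return out

    closed = erode(dilate(padded))
    sl = slice(2 * r, -2 * r)
    return closed[sl, sl, sl]


def monte_carlo_krogh_fraction(
    spacing_um: float, vessel_radius_um: float, d_um: float,
    n_points: int = 1_000_000, seed: int = 0,
) -> float:
    """Point-sampling estimate of the lattice coverage fraction: a uniform
    point in the unit cell centered on a capillary axis is covered iff its
    axial distance is <= vessel_radius + d."""
    rng = np.random.default_rng(seed)
    h = spacing_um / 2.0
    xy = rng.uniform(-h, h, size=(n_points, 2))
    r = np.hypot(xy[:, 0], xy[:, 1])
    return float(np.mean(r <= vessel_radius_um + d_um))


def exact_permutation_p(a, b) -> float:
    """Exact two-sided permutation p for the pooled t statistic: the fraction
    of all group assignments whose |t| is at least the observed |t|."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    na = len(a)

    def tstat(x, y):
        x = np.asarray(x)
        y = np.asarray(y)
        df = x.size + y.size - 2
        sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
        se = math.sqrt(sp2 * (1 / x.size + 1 / y.size))
        return (x.mean() - y.mean()) / se if se > 0 else math.inf

    t_obs = abs(tstat(a, b))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(tstat(ga, gb)) >= t_obs - 1e-12:
            count += 1
    return count / total
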