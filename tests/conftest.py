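"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own geometry code paths:
point-in-polygon is a hand-written ray-casting parity test, and surface
distances are exhaustive all-pairs minima.
"""

from __future__ import annotations

import numpy as np
import pytest

from iovkit import BinaryVolume, ImageGrid


def point_in_polygon(px: float, py: float, vertices) -> bool:
    """Ray-casting crossing-number test (strict interior, even-odd)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def brute_rasterize(contours, grid: ImageGrid) -> np.ndarray:
    """Even-odd parity over all rings, scanned voxel centre by voxel centre."""
    vox = np.zeros(grid.size, dtype=bool)
    xs, ys = grid.axis_centers(0), grid.axis_centers(1)
    by_slice: dict[int, list] = {}
    for c in contours:
        by_slice.setdefault(grid.slice_index(c.z), []).append(c)
    for k, rings in by_slice.items():
        for ix, x in enumerate(xs):
            for iy, y in enumerate(ys):
                parity = sum(point_in_polygon(x, y, c.vertices) for c in rings)
                vox[ix, iy, k] = parity % 2 == 1
    return vox


def brute_masd(a: BinaryVolume, b: BinaryVolume) -> float:
    """Exhaustive symmetric mean nearest surface-voxel distance, mm."""
    spacing = np.asarray(a.grid.spacing)
    surfs = []
    for v in (a, b):
        arr = v.voxels
        pts = []
        for idx in np.argwhere(arr):
            i, j, k = idx
            on_surface = False
            for d, ax in ((1, 0), (-1, 0), (1, 1), (-1, 1), (1, 2), (-1, 2)):
                nb = idx.copy()
                nb[ax] += d
                if (nb < 0).any() or (nb >= np.array(arr.shape)).any() or not arr[tuple(nb)]:
                    on_surface = True
                    break
            if on_surface:
                pts.append(idx * spacing)
        surfs.append(np.asarray(pts, dtype=float))
    pa, pb = surfs
    da = [np.min(np.linalg.norm(pb - p, axis=1)) for p in pa]
    db = [np.min(np.linalg.norm(pa - p, axis=1)) for p in pb]
    return (sum(da) + sum(db)) / (len(da) + len(db))


def star_polygon(rng: np.random.Generator, center, mean_r: float, n: int = 12):
    """A random star-shaped simple polygon (vertices off any voxel lattice)."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    rho = rng.uniform(0.4, 1.0, n) * mean_r
    return tuple(
        (center[0] + r * np.cos(t), center[1] + r * np.sin(t)) for r, t in zip(rho, theta)
    )


def make_volume(grid: ImageGrid, where) -> BinaryVolume:
    vox = np.zeros(grid.size, dtype=bool)
    vox[where] = True
    return BinaryVolume(grid, vox)


def random_mask(rng: np.random.Generator, grid: ImageGrid, p: float = 0.4) -> BinaryVolume:
    return BinaryVolume(grid, rng.random(grid.size) < p)


@pytest.fixture
def iso_grid() -> ImageGrid:
    """10×10×10 voxels at 1 mm isotropic, origin at 0."""
    return ImageGrid((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (10, 10, 10))


@pytest.fixture
def ct_grid() -> ImageGrid:
    """A small planning-CT-like grid: 1×1 mm in plane, 4 mm slices."""
    return ImageGrid((0.0, 0.0, 0.0), (1.0, 1.0, 4.0), (40, 40, 12))


@pytest.fixture(scope="session")
def random_mask_pairs():
    """100 seeded random mask pairs on a small grid, each pair non-empty."""
    grid = ImageGrid((0.0, 0.0, 0.0), (1.0, 1.0, 2.0), (12, 12, 6))
    rng = np.random.default_rng(20260920)
    pairs = []
    while len(pairs) < 100:
        a, b = random_mask(rng, grid), random_mask(rng, grid)
        if not a.is_empty() and not b.is_empty():
            pairs.append((a, b))
    return pairs
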