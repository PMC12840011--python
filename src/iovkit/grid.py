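"""Voxel lattice and binary occupancy volumes.

All geometry lives in physical millimetres in the DICOM patient convention:
x increases to the patient's left, y posteriorly, z cranially.  ``origin`` is
the *centre* of voxel (0, 0, 0); a voxel with index ``(i, j, k)`` has its
centre at ``origin + index * spacing``.  The grid extent is half-open per
axis: voxel ``i`` owns ``[c_i - d/2, c_i + d/2)`` along each axis, so a
contoured slice fills the full slice thickness ``dz``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import CoordinateError, GridMismatchError

__all__ = ["ImageGrid", "BinaryVolume", "boolean_op", "volume_cc"]

_TOL = 1e-6


@dataclass(frozen=True)
class ImageGrid:
    """A regular voxel lattice: origin (mm), per-axis spacing (mm), voxel counts."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.size) != 3:
            raise ValueError("origin, spacing and size must each have 3 components")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "size", tuple(int(v) for v in self.size))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        if any(n < 1 for n in self.size):
            raise ValueError(f"all sizes must be >= 1, got {self.size}")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical centre coordinates of all voxels along one axis (mm)."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.size[axis])

    def slice_z(self, k: int) -> float:
        if not 0 <= k < self.size[2]:
            raise CoordinateError(f"slice index {k} outside grid of {self.size[2]} slices")
        return self.origin[2] + k * self.spacing[2]

    def slice_index(self, z: float) -> int:
        """Index of the slice owning position ``z`` (|z - z_k| <= dz/2, ties to lower).

        Raises :class:`CoordinateError` when ``z`` falls outside the grid extent.
        """
        dz = self.spacing[2]
        u = (z - self.origin[2]) / dz
        k = math.ceil(u - 0.5 - 1e-9)  # equidistant z resolves to the lower slice
        if not 0 <= k < self.size[2] or abs(z - (self.origin[2] + k * dz)) > dz / 2 + _TOL:
            raise CoordinateError(
                f"z={z} mm matches no slice of grid (origin_z={self.origin[2]}, "
                f"dz={dz}, {self.size[2]} slices)"
            )
        return k

    def extent(self, axis: int) -> tuple[float, float]:
        """Half-open physical extent [lo, hi) of the grid along one axis, mm."""
        d = self.spacing[axis]
        lo = self.origin[axis] - d / 2
        return lo, lo + d * self.size[axis]

    def is_same(self, other: "ImageGrid", tol: float = _TOL) -> bool:
        return (
            self.size == other.size
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
        )


class BinaryVolume:
    """Grid-aligned boolean occupancy, indexed ``voxels[ix, iy, iz]``."""

    __slots__ = ("grid", "voxels")

    def __init__(self, grid: ImageGrid, voxels: np.ndarray):
        voxels = np.asarray(voxels, dtype=bool)
        if voxels.shape != tuple(grid.size):
            raise ValueError(f"voxel array shape {voxels.shape} != grid size {grid.size}")
        self.grid = grid
        self.voxels = voxels

    @classmethod
    def empty(cls, grid: ImageGrid) -> "BinaryVolume":
        return cls(grid, np.zeros(grid.size, dtype=bool))

    def count(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not self.voxels.any()

    def volume_cc(self) -> float:
        return self.count() * self.grid.voxel_volume_mm3 / 1000.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryVolume):
            return NotImplemented
        return self.grid.is_same(other.grid) and bool(np.array_equal(self.voxels, other.voxels))

    def __hash__(self) -> None:  # type: ignore[override]
        raise TypeError("BinaryVolume is unhashable")


def _require_same_grid(a: BinaryVolume, b: BinaryVolume) -> None:
    if not a.grid.is_same(b.grid):
        raise GridMismatchError(
            f"volumes are on different grids: {a.grid} vs {b.grid}; "
            "resampling is not supported"
        )


def boolean_op(a: BinaryVolume, b: BinaryVolume, op: str) -> BinaryVolume:
    """Element-wise set operation (``intersect``, ``union`` or ``minus``) on a shared grid."""
    _require_same_grid(a, b)
    if op == "intersect":
        v = a.voxels & b.voxels
    elif op == "union":
        v = a.voxels | b.voxels
    elif op == "minus":
        v = a.voxels & ~b.voxels
    else:
        raise ValueError(f"unknown boolean op {op!r}")
    return BinaryVolume(a.grid, v)


def volume_cc(volume: BinaryVolume) -> float:
    """Occupied volume in cm³: set-voxel count × dx·dy·dz / 1000."""
    return volume.volume_cc()
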