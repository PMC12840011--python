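"""Landmark-referenced border and width geometry.

The cranial and caudal borders of a structure are the z centres of its most
cranial and most caudal occupied slices.  Border positions are reported as
signed offsets to named anatomical landmarks — e.g. "4 mm below the floor of
the sphenoid sinus", "12 mm above the sternoclavicular joint" — with the
sign convention that a positive offset means the border lies in the stated
sense relative to the landmark.  Axial width is the occupied extent along
one in-plane axis on a named reference slice, outer-edge convention (a
single occupied voxel has width dx, not 0), reported in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, UndefinedMetricError
from .grid import BinaryVolume

__all__ = [
    "LandmarkSet",
    "craniocaudal_extent",
    "border_offset",
    "axial_width",
    "cohort_spread",
]

_AXES = {"x": 0, "y": 1}


@dataclass
class LandmarkSet:
    """Named landmark z positions (mm) and optional named reference slices
    for width measurement."""

    landmarks: dict[str, float] = field(default_factory=dict)
    reference_slices: dict[str, float] = field(default_factory=dict)

    def z(self, name: str) -> float:
        if name not in self.landmarks:
            raise ConfigError(f"unknown landmark {name!r}; have {sorted(self.landmarks)}")
        return self.landmarks[name]


def craniocaudal_extent(volume: BinaryVolume) -> tuple[float, float]:
    """(caudal z, cranial z) of the occupied slices, mm (slice centres)."""
    occupied = np.flatnonzero(volume.voxels.any(axis=(0, 1)))
    if occupied.size == 0:
        raise UndefinedMetricError("craniocaudal extent undefined for an empty volume")
    return volume.grid.slice_z(int(occupied[0])), volume.grid.slice_z(int(occupied[-1]))


def border_offset(extent_z: float, landmark_z: float, sense: str) -> float:
    """Signed distance of a border to a landmark, mm.

    ``sense="below"``: positive when the border lies caudal to the landmark
    (landmark_z − extent_z).  ``sense="above"``: positive when the border
    lies cranial to the landmark (extent_z − landmark_z).
    """
    if sense == "below":
        return landmark_z - extent_z
    if sense == "above":
        return extent_z - landmark_z
    raise ValueError(f"sense must be 'below' or 'above', got {sense!r}")


def axial_width(volume: BinaryVolume, z: float, axis: str = "x") -> float:
    """Occupied extent along ``axis`` on the slice at ``z``, in cm.

    Outer-edge convention: (max − min occupied centre + one voxel size)/10.
    An empty slice has width 0.  ``z`` outside the grid raises an error.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    k = volume.grid.slice_index(z)
    ax = _AXES[axis]
    sl = volume.voxels[:, :, k]
    occupied = np.flatnonzero(sl.any(axis=1 - ax))
    if occupied.size == 0:
        return 0.0
    d = volume.grid.spacing[ax]
    return ((occupied[-1] - occupied[0]) * d + d) / 10.0


def cohort_spread(values) -> tuple[float, float]:
    """(max pairwise difference, arithmetic mean) of a cohort of measurements."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cohort_spread needs at least one value")
    return float(v.max() - v.min()), float(v.mean())
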