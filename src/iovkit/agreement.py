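"""Multi-observer agreement statistics.

Volume dispersion is summarised by mean, sample SD (n−1 denominator) and the
coefficient of variation CoV = SD/mean.  Spatial agreement between observer
pairs uses the Dice similarity coefficient DSC = 2|A∩B|/(|A|+|B|) and the
Jaccard index J = |A∩B|/|A∪B|; cohort-level conformity uses the pairwise
conformity index

    CIpairs = Σ_{i<j} |Vi ∩ Vj|  /  Σ_{i<j} |Vi ∪ Vj|,

which, unlike the plain DSC average, is robust to the number of observers.
Boundary agreement is the mean absolute surface distance (MASD): the
symmetric mean, over both masks' surface-voxel centres, of the distance to
the nearest surface-voxel centre of the other mask, in mm.  Surface voxels
are set voxels with at least one face-adjacent unset (or out-of-grid)
neighbour.

Statistics for a structure are always computed over exactly the observers
who delineated it; omissions are never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import UndefinedMetricError
from .grid import BinaryVolume, boolean_op

__all__ = [
    "VolumeStats",
    "PairwiseAgreement",
    "volume_stats",
    "coefficient_of_variation",
    "dice",
    "jaccard",
    "ci_pairs",
    "masd",
    "pairwise_agreement",
    "round_half_away",
    "round_sig",
]


def round_half_away(x: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Reporting convention for printed tables (CoV to 2 decimals); banker's
    rounding would under-report exact .5 ties.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures, ties away from zero (volume cells)."""
    if x == 0:
        return 0.0
    nd = sig - 1 - math.floor(math.log10(abs(x)))
    return round_half_away(x, nd)


@dataclass(frozen=True)
class VolumeStats:
    """Per-structure volume dispersion across observers (volumes in cm³)."""

    structure_name: str
    n: int
    mean: float
    sd: float
    cov: float
    vmin: float
    vmax: float

    @property
    def range(self) -> tuple[float, float]:
        return (self.vmin, self.vmax)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CoV = SD / mean; undefined when the mean is 0 but the SD is not."""
    if mean > 0:
        return sd / mean
    if sd == 0:
        return 0.0
    raise UndefinedMetricError(f"CoV undefined: mean={mean}, sd={sd}")


def volume_stats(structure_name: str, volumes) -> VolumeStats:
    """Mean, sample SD (0 when n = 1), CoV and range of observer volumes."""
    v = np.asarray(list(volumes), dtype=float)
    if v.size == 0:
        raise ValueError(f"no volumes for {structure_name!r}")
    if (v < 0).any():
        raise ValueError("volumes must be non-negative")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return VolumeStats(
        structure_name=structure_name,
        n=int(v.size),
        mean=mean,
        sd=sd,
        cov=coefficient_of_variation(mean, sd),
        vmin=float(v.min()),
        vmax=float(v.max()),
    )


def _counts(a: BinaryVolume, b: BinaryVolume) -> tuple[int, int, int]:
    inter = boolean_op(a, b, "intersect").count()
    na, nb = a.count(), b.count()
    return inter, na, nb


def dice(a: BinaryVolume, b: BinaryVolume) -> float:
    """Dice similarity coefficient on voxel counts; undefined for two empty masks."""
    inter, na, nb = _counts(a, b)
    if na + nb == 0:
        raise UndefinedMetricError("DSC undefined: both masks are empty")
    return 2.0 * inter / (na + nb)


def jaccard(a: BinaryVolume, b: BinaryVolume) -> float:
    inter, na, nb = _counts(a, b)
    union = na + nb - inter
    if union == 0:
        raise UndefinedMetricError("Jaccard undefined: both masks are empty")
    return inter / union


def ci_pairs(masks: list[BinaryVolume]) -> float:
    """Pairwise conformity index over all unordered observer pairs.

    Equals the Jaccard index when n = 2 and is invariant under observer
    reordering.
    """
    if len(masks) < 2:
        raise ValueError(f"CIpairs needs at least 2 masks, got {len(masks)}")
    inter_sum = 0
    union_sum = 0
    counts = [m.count() for m in masks]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            inter, _, _ = _counts(masks[i], masks[j])
            inter_sum += inter
            union_sum += counts[i] + counts[j] - inter
    if union_sum == 0:
        raise UndefinedMetricError("CIpairs undefined: all masks are empty")
    return inter_sum / union_sum


_FACE6 = ndimage.generate_binary_structure(3, 1)


def _bbox_slices(arr: np.ndarray) -> tuple[slice, slice, slice] | None:
    """Tight bounding box of the set voxels, or None when empty."""
    out = []
    for ax in range(3):
        proj = np.any(arr, axis=tuple(i for i in range(3) if i != ax))
        nz = np.flatnonzero(proj)
        if nz.size == 0:
            return None
        out.append(slice(int(nz[0]), int(nz[-1]) + 1))
    return tuple(out)


def surface_voxels(volume: BinaryVolume) -> np.ndarray:
    """Indices (k, 3) of set voxels with a face-adjacent unset or out-of-grid neighbour."""
    box = _bbox_slices(volume.voxels)
    if box is None:
        return np.empty((0, 3), dtype=int)
    # eroding the tight crop is equivalent to eroding the full grid: voxels
    # beyond the bounding box and beyond the grid are unset either way
    sub = volume.voxels[box]
    interior = ndimage.binary_erosion(sub, structure=_FACE6, border_value=0)
    idx = np.argwhere(sub & ~interior)
    return idx + np.array([s.start for s in box])


def _masd_points(pa: np.ndarray, pb: np.ndarray) -> float:
    da, _ = cKDTree(pb).query(pa, workers=-1)
    db, _ = cKDTree(pa).query(pb, workers=-1)
    return float((da.sum() + db.sum()) / (len(da) + len(db)))


def masd(a: BinaryVolume, b: BinaryVolume) -> float:
    """Mean absolute surface distance in mm (symmetric over both surfaces)."""
    if a.is_empty() or b.is_empty():
        raise UndefinedMetricError("MASD undefined for an empty mask")
    if not a.grid.is_same(b.grid):
        from .errors import GridMismatchError

        raise GridMismatchError("MASD requires a shared grid")
    spacing = np.asarray(a.grid.spacing)
    return _masd_points(surface_voxels(a) * spacing, surface_voxels(b) * spacing)


@dataclass
class PairwiseAgreement:
    """Symmetric per-pair DSC and MASD matrices plus cohort CIpairs."""

    structure_name: str
    observer_ids: list[str]
    dsc_matrix: np.ndarray
    masd_matrix: np.ndarray
    ci_pairs: float

    def _offdiag(self, m: np.ndarray) -> np.ndarray:
        iu = np.triu_indices(len(self.observer_ids), k=1)
        return m[iu]

    def summary(self) -> dict[str, float]:
        d = self._offdiag(self.dsc_matrix)
        s = self._offdiag(self.masd_matrix)
        return {
            "dsc_mean": float(d.mean()),
            "dsc_min": float(d.min()),
            "dsc_max": float(d.max()),
            "masd_mean_mm": float(s.mean()),
            "masd_min_mm": float(s.min()),
            "masd_max_mm": float(s.max()),
            "ci_pairs": self.ci_pairs,
        }


def _pair_intersection(arrs, boxes, i: int, j: int) -> int:
    """Set-voxel count of arrs[i] & arrs[j], restricted to overlapping bboxes."""
    if boxes[i] is None or boxes[j] is None:
        return 0
    joint = []
    for a, b in zip(boxes[i], boxes[j]):
        lo, hi = max(a.start, b.start), min(a.stop, b.stop)
        if lo >= hi:
            return 0
        joint.append(slice(lo, hi))
    joint = tuple(joint)
    return int(np.count_nonzero(arrs[i][joint] & arrs[j][joint]))


def pairwise_agreement(
    structure_name: str, masks: dict[str, BinaryVolume]
) -> PairwiseAgreement:
    """All pairwise DSC/MASD plus CIpairs for one structure's observer masks.

    Equivalent to calling :func:`dice`, :func:`masd` and :func:`ci_pairs`
    pair by pair, but shares bounding boxes, surface extractions and each
    pair's intersection count across the metrics.
    """
    ids = list(masks)
    if len(ids) < 2:
        raise ValueError(f"pairwise agreement needs >= 2 observers for {structure_name!r}")
    n = len(ids)
    vols = [masks[o] for o in ids]
    grid = vols[0].grid
    for v in vols[1:]:
        if not v.grid.is_same(grid):
            from .errors import GridMismatchError

            raise GridMismatchError(f"masks of {structure_name!r} are on different grids")
    if any(v.is_empty() for v in vols):
        raise UndefinedMetricError(f"empty mask in cohort for {structure_name!r}")
    arrs = [v.voxels for v in vols]
    boxes = [_bbox_slices(a) for a in arrs]
    counts = [v.count() for v in vols]
    spacing = np.asarray(grid.spacing)
    surfaces = [surface_voxels(v) * spacing for v in vols]
    dsc = np.eye(n)
    sdist = np.zeros((n, n))
    inter_sum = 0
    union_sum = 0
    for i in range(n):
        for j in range(i + 1, n):
            inter = _pair_intersection(arrs, boxes, i, j)
            inter_sum += inter
            union_sum += counts[i] + counts[j] - inter
            dsc[i, j] = dsc[j, i] = 2.0 * inter / (counts[i] + counts[j])
            sdist[i, j] = sdist[j, i] = _masd_points(surfaces[i], surfaces[j])
    return PairwiseAgreement(
        structure_name=structure_name,
        observer_ids=ids,
        dsc_matrix=dsc,
        masd_matrix=sdist,
        ci_pairs=inter_sum / union_sum,
    )
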