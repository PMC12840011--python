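"""Planar contour model, multi-observer cohorts and rasterization.

A structure is a stack of closed planar polygons, one or more per CT slice,
each tagged as an outer boundary or a hole.  Rasterization sets a voxel iff
its centre lies inside the even-odd combination of all rings on its slice
(outer rings minus holes), the behaviour of common treatment-planning
systems.  Structures supplied as pre-rasterized masks bypass polygon filling
but must declare the same grid.

I/O covers three routes: a portable JSON contour dialect (defined here and
round-trip safe), read-only DICOM-RT STRUCT via pydicom, and NIfTI binary
masks via nibabel.  ROI names are mapped onto a controlled vocabulary
through a user-editable CSV alias table; unmapped names are kept verbatim
with a warning.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from functools import reduce
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.validation import make_valid

from .errors import ContourParseError, CoordinateError, GridMismatchError
from .grid import BinaryVolume, ImageGrid

__all__ = [
    "CANONICAL_STRUCTURES",
    "PlanarContour",
    "StructureDelineation",
    "ObserverCohort",
    "rasterize",
    "read_contours",
    "write_contours",
    "read_alias_table",
    "read_mask_nifti",
    "write_mask_nifti",
]

log = logging.getLogger(__name__)

#: Controlled vocabulary of the delineated target volumes and organs at risk.
#: Arbitrary additional names (e.g. nodal levels) are allowed and kept verbatim.
CANONICAL_STRUCTURES = frozenset(
    {
        "PTV1",
        "PTV2",
        "brainstem",
        "pituitary",
        "inner ear L",
        "inner ear R",
        "optic chiasm",
        "spinal canal",
        "optic nerve L",
        "optic nerve R",
        "eye lens L",
        "eye lens R",
        "TMJ L",
        "TMJ R",
        "parotid L",
        "parotid R",
        "submandibular L",
        "submandibular R",
    }
)


@dataclass(frozen=True)
class PlanarContour:
    """One closed planar polygon at slice position ``z`` (mm).

    ``role`` is ``"outer"`` or ``"hole"``; the first vertex is implicitly
    joined to the last.
    """

    z: float
    vertices: tuple[tuple[float, float], ...]
    role: str = "outer"

    def __post_init__(self) -> None:
        if self.role not in ("outer", "hole"):
            raise ValueError(f"contour role must be 'outer' or 'hole', got {self.role!r}")
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ContourParseError(
                f"polygon at z={self.z} has {len(verts)} vertices; at least 3 required"
            )
        object.__setattr__(self, "vertices", verts)
        if abs(self.signed_area()) <= 0.0:
            raise ContourParseError(f"polygon at z={self.z} has zero area")

    def signed_area(self) -> float:
        v = np.asarray(self.vertices)
        x, y = v[:, 0], v[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class StructureDelineation:
    """One observer's delineation of one named structure."""

    observer_id: str
    structure_name: str
    contours: list[PlanarContour] = field(default_factory=list)
    mask: BinaryVolume | None = None

    def __post_init__(self) -> None:
        if not self.structure_name:
            raise ValueError("structure_name must be non-empty")
        if self.mask is None and not self.contours:
            raise ValueError(
                f"delineation {self.observer_id}/{self.structure_name} has neither "
                "contours nor a mask"
            )


def _slice_region(rings: list[PlanarContour]):
    """Even-odd combination of all rings on a slice as a shapely geometry."""
    polys = []
    for c in rings:
        p = Polygon(c.vertices)
        if not p.is_valid:
            p = make_valid(p)
        polys.append(p)
    return reduce(lambda a, b: a.symmetric_difference(b), polys)


def rasterize(delineation: StructureDelineation, grid: ImageGrid) -> BinaryVolume:
    """Fill a delineation onto the grid: voxel centre-in-polygon, even-odd rule.

    Pre-rasterized masks are passed through after a grid check.  Raises
    :class:`CoordinateError` when a contour lies outside the grid extent.
    """
    if delineation.mask is not None:
        if not delineation.mask.grid.is_same(grid):
            raise GridMismatchError(
                f"mask for {delineation.observer_id}/{delineation.structure_name} "
                f"declares grid {delineation.mask.grid}, expected {grid}"
            )
        return delineation.mask

    xlo, xhi = grid.extent(0)
    ylo, yhi = grid.extent(1)
    by_slice: dict[int, list[PlanarContour]] = {}
    for c in delineation.contours:
        try:
            k = grid.slice_index(c.z)
        except CoordinateError as exc:
            raise CoordinateError(
                f"contour of {delineation.observer_id}/{delineation.structure_name}: {exc}"
            ) from exc
        v = np.asarray(c.vertices)
        if v[:, 0].min() < xlo or v[:, 0].max() >= xhi or v[:, 1].min() < ylo or v[:, 1].max() >= yhi:
            raise CoordinateError(
                f"contour of {delineation.observer_id}/{delineation.structure_name} at "
                f"z={c.z} extends outside the grid extent "
                f"x[{xlo},{xhi}) y[{ylo},{yhi})"
            )
        by_slice.setdefault(k, []).append(c)

    xs = grid.axis_centers(0)
    ys = grid.axis_centers(1)
    vox = np.zeros(grid.size, dtype=bool)
    for k, rings in by_slice.items():
        region = _slice_region(rings)
        if region.is_empty:
            continue
        bx0, by0, bx1, by1 = region.bounds
        i0, i1 = np.searchsorted(xs, [bx0, bx1]) + [0, 1]
        j0, j1 = np.searchsorted(ys, [by0, by1]) + [0, 1]
        i0, j0 = max(i0 - 1, 0), max(j0 - 1, 0)
        if i0 >= i1 or j0 >= j1:
            continue
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        inside = shapely.contains_xy(region, gx.ravel(), gy.ravel())
        vox[i0:i1, j0:j1, k] |= inside.reshape(gx.shape)
    return BinaryVolume(grid, vox)


@dataclass
class ObserverCohort:
    """All observers' delineations on one shared grid.

    Observers who omitted a structure are simply absent from that
    structure's entries — omissions are never represented as empty volumes,
    and the per-structure observer count N reflects who actually contoured.
    """

    grid: ImageGrid
    observers: list[str]
    structures: dict[tuple[str, str], StructureDelineation] = field(default_factory=dict)

    def add(self, d: StructureDelineation) -> None:
        """Add a delineation; same-named duplicates per observer are merged by union."""
        if d.observer_id not in self.observers:
            self.observers.append(d.observer_id)
        key = (d.observer_id, d.structure_name)
        if key in self.structures:
            log.warning(
                "observer %s has duplicate structure %r; merging by union",
                d.observer_id,
                d.structure_name,
            )
            prev = self.structures[key]
            if prev.mask is not None or d.mask is not None:
                a = rasterize(prev, self.grid).voxels | rasterize(d, self.grid).voxels
                self.structures[key] = StructureDelineation(
                    d.observer_id, d.structure_name, mask=BinaryVolume(self.grid, a)
                )
            else:
                self.structures[key] = StructureDelineation(
                    d.observer_id, d.structure_name, contours=prev.contours + d.contours
                )
        else:
            self.structures[key] = d

    def structure_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, name in self.structures:
            seen.setdefault(name)
        return list(seen)

    def observers_with(self, structure_name: str) -> list[str]:
        return [o for o in self.observers if (o, structure_name) in self.structures]

    def n(self, structure_name: str) -> int:
        return len(self.observers_with(structure_name))

    def volume(self, observer_id: str, structure_name: str) -> BinaryVolume:
        return rasterize(self.structures[(observer_id, structure_name)], self.grid)

    def volumes(self, structure_name: str) -> dict[str, BinaryVolume]:
        """Rasterized masks of every observer who delineated the structure."""
        return {o: self.volume(o, structure_name) for o in self.observers_with(structure_name)}


# ---------------------------------------------------------------------------
# alias table


def read_alias_table(path: str | Path) -> dict[str, str]:
    """CSV with columns raw_name, canonical_name → mapping."""
    table: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"raw_name", "canonical_name"} <= set(
            reader.fieldnames
        ):
            raise ContourParseError(
                f"alias table {path} must have columns raw_name, canonical_name"
            )
        for row in reader:
            table[row["raw_name"].strip()] = row["canonical_name"].strip()
    return table


def _canonical_name(raw: str, alias: dict[str, str] | None) -> str:
    if alias and raw in alias:
        return alias[raw]
    if raw in CANONICAL_STRUCTURES:
        return raw
    warnings.warn(
        f"structure name {raw!r} is not in the controlled vocabulary and has no alias; "
        "keeping it verbatim",
        stacklevel=3,
    )
    return raw


# ---------------------------------------------------------------------------
# JSON contour dialect

_DIALECTS = ("json", "dicom-rt")


def write_contours(cohort: ObserverCohort, path: str | Path) -> None:
    """Write a cohort in the portable JSON contour dialect (lengths in mm)."""
    obs_out = []
    for oid in cohort.observers:
        structs = []
        for (o, name), d in cohort.structures.items():
            if o != oid:
                continue
            if d.mask is not None:
                raise ValueError(
                    f"{o}/{name} is mask-backed; the JSON dialect stores polygons only"
                )
            structs.append(
                {
                    "name": name,
                    "contours": [
                        {"z": c.z, "role": c.role, "vertices": [list(v) for v in c.vertices]}
                        for c in d.contours
                    ],
                }
            )
        obs_out.append({"id": oid, "structures": structs})
    doc = {
        "grid": {
            "origin": list(cohort.grid.origin),
            "spacing": list(cohort.grid.spacing),
            "size": list(cohort.grid.size),
        },
        "observers": obs_out,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _read_json(path: Path, alias: dict[str, str] | None) -> ObserverCohort:
    try:
        doc = json.loads(path.read_text())
        g = doc["grid"]
        grid = ImageGrid(tuple(g["origin"]), tuple(g["spacing"]), tuple(g["size"]))
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise ContourParseError(f"{path}: malformed JSON contour file: {exc}") from exc
    cohort = ObserverCohort(grid, [])
    for obs in doc.get("observers", []):
        oid = str(obs["id"])
        if oid not in cohort.observers:
            cohort.observers.append(oid)
        for s in obs.get("structures", []):
            name = _canonical_name(str(s["name"]), alias)
            try:
                contours = [
                    PlanarContour(
                        z=float(c["z"]),
                        vertices=tuple((float(x), float(y)) for x, y in c["vertices"]),
                        role=c.get("role", "outer"),
                    )
                    for c in s["contours"]
                ]
            except ContourParseError as exc:
                raise ContourParseError(f"{path}: ROI {s['name']!r} of observer {oid}: {exc}") from exc
            for c in contours:  # fail early with the offending ROI named
                try:
                    grid.slice_index(c.z)
                except CoordinateError as exc:
                    raise CoordinateError(
                        f"{path}: ROI {s['name']!r} of observer {oid}: {exc}"
                    ) from exc
            cohort.add(StructureDelineation(oid, name, contours=contours))
    return cohort


# ---------------------------------------------------------------------------
# DICOM-RT STRUCT (read-only)


def _read_dicom_rt_file(path: Path, grid: ImageGrid, alias, cohort: ObserverCohort) -> None:
    import pydicom

    ds = pydicom.dcmread(path)
    oid = path.stem
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    for rc in getattr(ds, "ROIContourSequence", []):
        raw = names.get(int(rc.ReferencedROINumber), f"ROI{rc.ReferencedROINumber}")
        contours = []
        for item in getattr(rc, "ContourSequence", []):
            pts = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            if len(pts) < 3:
                raise ContourParseError(
                    f"{path}: ROI {raw!r} has a contour with {len(pts)} points"
                )
            zs = pts[:, 2]
            if np.ptp(zs) > 1e-3:
                raise ContourParseError(f"{path}: ROI {raw!r} has a non-planar contour")
            contours.append(
                PlanarContour(z=float(zs.mean()), vertices=tuple(map(tuple, pts[:, :2])))
            )
        if contours:
            name = _canonical_name(raw, alias)
            cohort.add(StructureDelineation(oid, name, contours=contours))


def read_contours(
    path: str | Path,
    dialect: str = "json",
    grid: ImageGrid | None = None,
    alias: dict[str, str] | None = None,
) -> ObserverCohort:
    """Read a multi-observer cohort.

    ``json`` reads one self-describing file in the package's contour dialect.
    ``dicom-rt`` reads a DICOM-RT STRUCT file (one observer, id = file stem)
    or a directory of them, and requires an explicit ``grid`` since RT STRUCT
    carries no voxel lattice of its own.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "json":
        return _read_json(path, alias)
    if grid is None:
        raise ValueError("dialect 'dicom-rt' requires an explicit grid")
    cohort = ObserverCohort(grid, [])
    files = sorted(path.glob("*.dcm")) if path.is_dir() else [path]
    if not files:
        raise ContourParseError(f"no .dcm files under {path}")
    for f in files:
        _read_dicom_rt_file(f, grid, alias, cohort)
    return cohort


# ---------------------------------------------------------------------------
# NIfTI binary masks


def _grid_affine(grid: ImageGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def read_mask_nifti(path: str | Path, grid: ImageGrid, tol: float = 1e-3) -> BinaryVolume:
    """Read a binary mask whose affine must match the declared grid."""
    import nibabel as nib

    img = nib.load(str(path))
    if not np.allclose(img.affine, _grid_affine(grid), atol=tol):
        raise GridMismatchError(
            f"{path}: NIfTI affine does not match the declared grid "
            f"(expected diag{grid.spacing} + origin {grid.origin})"
        )
    data = np.asanyarray(img.dataobj)
    if data.shape != tuple(grid.size):
        raise GridMismatchError(f"{path}: shape {data.shape} != grid size {grid.size}")
    return BinaryVolume(grid, data > 0)


def write_mask_nifti(volume: BinaryVolume, path: str | Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(volume.voxels.astype(np.uint8), _grid_affine(volume.grid))
    nib.save(img, str(path))
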