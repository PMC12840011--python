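"""Synthetic multi-observer delineation cohorts with known ground truth.

Observer disagreement on a base shape is decomposed into the three effects
that dominate real contouring variation:

* a **systematic margin** per observer, δ_i ~ Normal(μ_δ, σ_δ) mm, applied
  as an isotropic dilation (different habits in safety-margin application);
* **smooth boundary noise**: a low-order angular Fourier perturbation of
  the contour radius with a configurable standard deviation (ambiguity of
  soft-tissue boundaries);
* **craniocaudal truncation**: a per-observer caudal cut plane, offsets in
  multiples of the slice thickness (differing choices of the caudal border
  slice).

Structures may additionally be omitted per observer — omitted structures
are absent from the cohort, never empty.  Everything is deterministic given
the seed.  ``study_cohort_spec`` returns the default cohort emulating the
study conditions: ten observers on a 1×1×4 mm grid of 512×512×80 voxels,
two target volumes and the full organ-at-risk set with paper-scale volumes,
box-shaped nodal levels, and the two craniocaudal landmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .contours import ObserverCohort, PlanarContour, StructureDelineation, rasterize
from .errors import ConfigError
from .grid import ImageGrid
from .landmarks import LandmarkSet
from .levels import NodalLevelSet

__all__ = [
    "ShapeSpec",
    "CohortSpec",
    "GroundTruth",
    "ObserverTruth",
    "analytic_volume",
    "generate",
    "levels_as_cohort",
    "nodal_levels",
    "landmark_set",
    "study_cohort_spec",
]

_KINDS = ("sphere", "ellipsoid", "box", "tube")
_HARMONICS = (2, 3, 4, 5)


@dataclass(frozen=True)
class ShapeSpec:
    """A base geometric structure: centre (mm) and per-axis half-extents (mm).

    ``radii`` are the semi-axes (ellipsoid), half-sides (box), or
    (r, r, half-length) for a z-aligned tube; a sphere uses radii[0].
    """

    name: str
    kind: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    omission_prob: float = 0.0
    omit_observers: tuple[int, ...] = ()
    truncatable: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"unsupported shape kind {self.kind!r}; expected {_KINDS}")
        if not 0.0 <= self.omission_prob <= 1.0:
            raise ConfigError(f"omission_prob must lie in [0, 1], got {self.omission_prob}")
        if any(r <= 0 for r in self.radii):
            raise ConfigError(f"shape {self.name!r} has non-positive radii {self.radii}")


def analytic_volume(shape: ShapeSpec, margin: float = 0.0) -> float:
    """Closed-form volume in cm³ of the shape dilated by ``margin`` mm."""
    a, b, c = (r + margin for r in shape.radii)
    if shape.kind == "sphere":
        r = shape.radii[0] + margin
        mm3 = 4.0 / 3.0 * math.pi * r**3
    elif shape.kind == "ellipsoid":
        mm3 = 4.0 / 3.0 * math.pi * a * b * c
    elif shape.kind == "box":
        mm3 = 8.0 * a * b * c
    elif shape.kind == "tube":
        mm3 = math.pi * a * b * (2.0 * c)
    else:  # pragma: no cover - guarded in __post_init__
        raise ConfigError(f"unsupported shape kind {shape.kind!r}")
    return mm3 / 1000.0


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort (all lengths in mm)."""

    seed: int
    n_observers: int = 10
    grid: ImageGrid = ImageGrid((0.0, 0.0, 0.0), (1.0, 1.0, 4.0), (512, 512, 80))
    shapes: tuple[ShapeSpec, ...] = ()
    margin_mean: float = 0.0
    margin_sd: float = 0.0
    boundary_noise_sd: float = 0.0
    caudal_truncation_offsets: tuple[float, ...] | None = None
    truncation_reference_z: float | None = None
    levels: tuple[ShapeSpec, ...] = ()
    landmarks: dict[str, float] = field(default_factory=dict)
    reference_slices: dict[str, float] = field(default_factory=dict)
    n_vertices: int = 96

    def __post_init__(self) -> None:
        if self.n_observers < 2:
            raise ConfigError(f"need at least 2 observers, got {self.n_observers}")
        if self.margin_sd < 0 or self.boundary_noise_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.caudal_truncation_offsets is not None and len(
            self.caudal_truncation_offsets
        ) != self.n_observers:
            raise ConfigError("caudal_truncation_offsets must have one entry per observer")


@dataclass(frozen=True)
class ObserverTruth:
    """Realized error-model parameters of one observer."""

    margin_mm: float
    truncation_z: float | None
    omitted: tuple[str, ...]


@dataclass(frozen=True)
class GroundTruth:
    """The generator's exact knowledge of the cohort it produced."""

    shapes: dict[str, ShapeSpec]
    analytic_volumes_cc: dict[str, float]
    observers: dict[str, ObserverTruth]


def _polar_radius(kind: str, A: float, B: float, theta: np.ndarray) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    if kind == "box":
        with np.errstate(divide="ignore"):
            rx = np.where(np.abs(c) > 1e-12, A / np.abs(c), np.inf)
            ry = np.where(np.abs(s) > 1e-12, B / np.abs(s), np.inf)
        return np.minimum(rx, ry)
    return A * B / np.sqrt((B * c) ** 2 + (A * s) ** 2)


def _thetas(kind: str, A: float, B: float, n: int) -> np.ndarray:
    theta = 2.0 * math.pi * np.arange(n) / n
    if kind == "box":  # sample the exact corners so rectangles stay rectangles
        corner = math.atan2(B, A)
        corners = np.array([corner, math.pi - corner, math.pi + corner, -corner])
        theta = np.unique(np.concatenate([theta, corners % (2 * math.pi)]))
    return theta


def _cross_section(shape: ShapeSpec, delta: float, zrel: float) -> tuple[float, float] | None:
    a, b, c = (r + delta for r in shape.radii)
    if shape.kind in ("sphere", "ellipsoid"):
        if shape.kind == "sphere":
            a = b = c = shape.radii[0] + delta
        s2 = 1.0 - (zrel / c) ** 2
        if s2 <= 0.0:
            return None
        return a * math.sqrt(s2), b * math.sqrt(s2)
    if abs(zrel) > c:
        return None
    return a, b


def _noise_coeffs(rng: np.random.Generator, sd: float) -> np.ndarray:
    """Fourier coefficients (cos/sin per harmonic) with angular SD ``sd`` mm."""
    coeffs = rng.standard_normal(2 * len(_HARMONICS))
    if sd <= 0:
        return np.zeros_like(coeffs)
    norm = math.sqrt(float(np.sum(coeffs**2)) / 2.0)
    return coeffs * (sd / norm) if norm > 0 else coeffs


def _noise(coeffs: np.ndarray, theta: np.ndarray) -> np.ndarray:
    out = np.zeros_like(theta)
    for idx, k in enumerate(_HARMONICS):
        out += coeffs[2 * idx] * np.cos(k * theta) + coeffs[2 * idx + 1] * np.sin(k * theta)
    return out


def _shape_contours(
    shape: ShapeSpec,
    grid: ImageGrid,
    delta: float,
    coeffs: np.ndarray,
    n_vertices: int,
    z_cut: float | None,
) -> list[PlanarContour]:
    cx, cy, cz = shape.center
    xlo, xhi = grid.extent(0)
    ylo, yhi = grid.extent(1)
    contours = []
    for k in range(grid.size[2]):
        z = grid.slice_z(k)
        if z_cut is not None and z < z_cut - 1e-9:
            continue
        sec = _cross_section(shape, delta, z - cz)
        if sec is None:
            continue
        A, B = sec
        theta = _thetas(shape.kind, A, B, n_vertices)
        rho = _polar_radius(shape.kind, A, B, theta) + _noise(coeffs, theta)
        rho = np.maximum(rho, 0.1)
        xs = cx + rho * np.cos(theta)
        ys = cy + rho * np.sin(theta)
        if xs.min() < xlo or xs.max() >= xhi or ys.min() < ylo or ys.max() >= yhi:
            raise ConfigError(
                f"shape {shape.name!r} exceeds the grid extent after dilation "
                f"by {delta:.2f} mm at z={z}"
            )
        contours.append(PlanarContour(z=z, vertices=tuple(zip(xs, ys))))
    return contours


def _default_truncation_reference(spec: CohortSpec) -> float | None:
    if spec.caudal_truncation_offsets is None:
        return None
    if spec.truncation_reference_z is not None:
        return spec.truncation_reference_z
    trunc = [s for s in spec.shapes if s.truncatable]
    if not trunc:
        return None
    s = trunc[0]
    z = s.center[2] - s.radii[2] / 2.0
    oz, dz = spec.grid.origin[2], spec.grid.spacing[2]
    k = int(np.clip(round((z - oz) / dz), 0, spec.grid.size[2] - 1))
    return oz + k * dz


def generate(spec: CohortSpec) -> tuple[ObserverCohort, GroundTruth]:
    """Produce a multi-observer cohort plus its exact ground truth.

    Deterministic given ``spec.seed``: random draws occur in a fixed order
    (per-observer margins, then per structure × observer the omission and
    noise-coefficient draws), independent of parameter values.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_observers
    obs_ids = [f"RO{i + 1:02d}" for i in range(n)]
    deltas = spec.margin_mean + spec.margin_sd * rng.standard_normal(n)
    z_ref = _default_truncation_reference(spec)

    cohort = ObserverCohort(spec.grid, list(obs_ids))
    omitted: dict[str, list[str]] = {o: [] for o in obs_ids}
    for shape in spec.shapes:
        min_r = min(shape.radii)
        for i, oid in enumerate(obs_ids):
            omit_draw = rng.uniform()
            coeffs = _noise_coeffs(rng, spec.boundary_noise_sd)
            if i in shape.omit_observers or omit_draw < shape.omission_prob:
                omitted[oid].append(shape.name)
                continue
            delta = max(float(deltas[i]), -min_r / 2.0)
            z_cut = None
            if shape.truncatable and spec.caudal_truncation_offsets is not None:
                z_cut = z_ref + spec.caudal_truncation_offsets[i]
            contours = _shape_contours(
                shape, spec.grid, delta, coeffs, spec.n_vertices, z_cut
            )
            if not contours:
                raise ConfigError(
                    f"shape {shape.name!r} produced no contours for observer {oid}"
                )
            cohort.add(StructureDelineation(oid, shape.name, contours=contours))

    truth = GroundTruth(
        shapes={s.name: s for s in spec.shapes},
        analytic_volumes_cc={s.name: analytic_volume(s) for s in spec.shapes},
        observers={
            oid: ObserverTruth(
                margin_mm=float(deltas[i]),
                truncation_z=(
                    z_ref + spec.caudal_truncation_offsets[i]
                    if spec.caudal_truncation_offsets is not None and z_ref is not None
                    else None
                ),
                omitted=tuple(omitted[oid]),
            )
            for i, oid in enumerate(obs_ids)
        },
    )
    return cohort, truth


def nodal_levels(spec: CohortSpec) -> NodalLevelSet:
    """Rasterize the spec's level shapes (no observer model) onto the grid."""
    zero = np.zeros(2 * len(_HARMONICS))
    out = {}
    for shape in spec.levels:
        contours = _shape_contours(shape, spec.grid, 0.0, zero, spec.n_vertices, None)
        d = StructureDelineation("__levels__", shape.name, contours=contours)
        out[shape.name] = rasterize(d, spec.grid)
    return NodalLevelSet(out)


def levels_as_cohort(spec: CohortSpec) -> ObserverCohort:
    """The spec's level shapes as a single-pseudo-observer contour cohort
    (for emission in the JSON dialect)."""
    zero = np.zeros(2 * len(_HARMONICS))
    cohort = ObserverCohort(spec.grid, ["__levels__"])
    for shape in spec.levels:
        contours = _shape_contours(shape, spec.grid, 0.0, zero, spec.n_vertices, None)
        cohort.add(StructureDelineation("__levels__", shape.name, contours=contours))
    return cohort


def landmark_set(spec: CohortSpec) -> LandmarkSet:
    return LandmarkSet(dict(spec.landmarks), dict(spec.reference_slices))


# ---------------------------------------------------------------------------
# the default study-scale cohort


def _mirror(name_l: str, name_r: str, shape: ShapeSpec) -> tuple[ShapeSpec, ShapeSpec]:
    cx, cy, cz = shape.center
    left = replace(shape, name=name_l)
    right = replace(shape, name=name_r, center=(2 * 256.0 - cx, cy, cz))
    return left, right


def study_cohort_spec(seed: int) -> CohortSpec:
    """The default synthetic stand-in for the study's ten-observer dataset.

    Base volumes match the reported per-structure means; the observer model
    uses a 2 ± 1 mm systematic margin, 1.5 mm boundary noise, and caudal
    truncation offsets spanning 20 mm in slice-thickness steps.  Nodal
    levels are box stand-ins placed so that the deeper caudal levels pass
    the 70% rule only for observers with caudal-enough PTV1 borders.
    """
    shapes = [
        ShapeSpec("PTV1", "tube", (256.0, 256.0, 140.0), (80.0, 40.0, 42.0), truncatable=True),
        ShapeSpec("PTV2", "ellipsoid", (256.0, 245.0, 150.0), (55.0, 45.0, 38.0)),
        ShapeSpec("brainstem", "tube", (256.0, 290.0, 200.0), (11.0, 11.0, 34.0)),
        ShapeSpec("spinal canal", "tube", (256.0, 300.0, 130.0), (7.5, 7.5, 96.0)),
        ShapeSpec("pituitary", "sphere", (256.0, 270.0, 240.0), (5.5, 5.5, 5.5),
                  omit_observers=(3, 6, 9)),
        ShapeSpec("optic chiasm", "ellipsoid", (256.0, 265.0, 248.0), (15.0, 7.0, 4.0),
                  omit_observers=(5,)),
        *_mirror("inner ear L", "inner ear R",
                 ShapeSpec("inner ear L", "sphere", (320.0, 280.0, 236.0), (6.3, 6.3, 6.3))),
        *_mirror("optic nerve L", "optic nerve R",
                 ShapeSpec("optic nerve L", "ellipsoid", (285.0, 250.0, 244.0), (18.0, 4.0, 5.0))),
        *_mirror("eye lens L", "eye lens R",
                 ShapeSpec("eye lens L", "ellipsoid", (330.0, 215.0, 244.0), (4.5, 4.5, 3.0))),
        *_mirror("TMJ L", "TMJ R",
                 ShapeSpec("TMJ L", "ellipsoid", (360.0, 260.0, 224.0), (8.0, 8.0, 7.5),
                           omit_observers=(2, 8))),
        *_mirror("parotid L", "parotid R",
                 ShapeSpec("parotid L", "ellipsoid", (370.0, 280.0, 200.0), (22.0, 15.0, 14.5))),
        *_mirror("submandibular L", "submandibular R",
                 ShapeSpec("submandibular L", "ellipsoid", (300.0, 230.0, 170.0), (16.0, 11.0, 11.8))),
    ]
    box = "box"
    levels = [
        ShapeSpec("IIa left", box, (200.0, 256.0, 150.0), (15.0, 15.0, 10.0)),
        ShapeSpec("IIa right", box, (312.0, 256.0, 150.0), (15.0, 15.0, 10.0)),
        ShapeSpec("IIb left", box, (200.0, 256.0, 168.0), (15.0, 15.0, 8.0)),
        ShapeSpec("IIb right", box, (312.0, 256.0, 168.0), (15.0, 15.0, 8.0)),
        ShapeSpec("III left", box, (200.0, 256.0, 130.0), (15.0, 15.0, 8.0)),
        ShapeSpec("III right", box, (312.0, 256.0, 130.0), (15.0, 15.0, 8.0)),
        ShapeSpec("IVa left", box, (200.0, 256.0, 118.0), (12.0, 12.0, 6.0)),
        ShapeSpec("IVa right", box, (312.0, 256.0, 126.0), (12.0, 12.0, 6.0)),
        ShapeSpec("IVb left", box, (200.0, 256.0, 108.0), (12.0, 12.0, 4.0)),
        ShapeSpec("IVb right", box, (312.0, 256.0, 110.0), (12.0, 12.0, 6.0)),
        ShapeSpec("Ia", box, (256.0, 230.0, 110.0), (10.0, 10.0, 6.0)),
        ShapeSpec("Va left", box, (190.0, 256.0, 110.0), (10.0, 10.0, 6.0)),
        ShapeSpec("Vc right", box, (312.0, 256.0, 116.0), (10.0, 10.0, 8.0)),
        ShapeSpec("VIa left", box, (230.0, 180.0, 110.0), (10.0, 10.0, 6.0)),
        ShapeSpec("VIa right", box, (282.0, 180.0, 110.0), (10.0, 10.0, 6.0)),
    ]
    return CohortSpec(
        seed=seed,
        n_observers=10,
        shapes=tuple(shapes),
        margin_mean=2.0,
        margin_sd=1.0,
        boundary_noise_sd=1.5,
        caudal_truncation_offsets=(0.0, -4.0, -4.0, -8.0, -8.0, -8.0, -12.0, -16.0, -16.0, -20.0),
        truncation_reference_z=120.0,
        levels=tuple(levels),
        landmarks={"sphenoid_sinus_floor": 186.0, "sternoclavicular_joint": 100.0},
        reference_slices={"supraclavicular": 124.0},
    )
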