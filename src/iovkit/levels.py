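"""Lymph-node-level inclusion in the planning target volume.

A nodal level counts as included in an observer's PTV when the overlapping
volume exceeds a configurable fraction of the level's own volume — strictly
greater than 70% by default ("more than 70%"), so a fraction of exactly the
threshold does not count.  Fractions are computed on voxel counts of the
shared grid, never on re-rounded cm³ values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .contours import ObserverCohort
from .errors import ConfigError, UndefinedMetricError
from .grid import BinaryVolume, boolean_op

__all__ = [
    "NodalLevelSet",
    "LevelInclusionResult",
    "overlap_fraction",
    "is_included",
    "level_coverage_table",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.70


@dataclass
class NodalLevelSet:
    """Named nodal-level masks on the common grid (left/right levels are
    independent entries keyed by name)."""

    levels: dict[str, BinaryVolume] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, vol in self.levels.items():
            if vol.is_empty():
                raise ValueError(f"nodal level {name!r} has zero volume")


@dataclass
class LevelInclusionResult:
    """Per-level inclusion verdicts across the observer cohort."""

    level_name: str
    fractions: dict[str, float]  # observer -> overlap fraction in [0, 1]
    included: dict[str, bool]
    count: int
    n_observers: int

    @property
    def covered_by_all(self) -> bool:
        return self.count == self.n_observers

    @property
    def covered_by_none(self) -> bool:
        return self.count == 0


def overlap_fraction(level: BinaryVolume, ptv: BinaryVolume) -> float:
    """|level ∩ PTV| / |level| on voxel counts."""
    nl = level.count()
    if nl == 0:
        raise UndefinedMetricError("overlap fraction undefined for an empty level")
    return boolean_op(level, ptv, "intersect").count() / nl


def is_included(fraction: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Strictly-greater-than comparison against the inclusion threshold."""
    if not 0.0 < threshold < 1.0:
        raise ConfigError(f"inclusion threshold must lie in (0, 1), got {threshold}")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"overlap fraction must lie in [0, 1], got {fraction}")
    return bool(fraction > threshold)


def level_coverage_table(
    cohort: ObserverCohort,
    levels: NodalLevelSet,
    ptv_name: str = "PTV1",
    threshold: float = DEFAULT_THRESHOLD,
) -> list[LevelInclusionResult]:
    """Inclusion verdicts for every level against every observer's PTV.

    Observers lacking the named PTV are excluded with a logged warning; the
    per-level observer count refers to the observers actually evaluated.
    """
    have = cohort.observers_with(ptv_name)
    for o in cohort.observers:
        if o not in have:
            log.warning("observer %s has no structure %r; excluded from level coverage", o, ptv_name)
    if not have:
        raise ConfigError(f"no observer delineated {ptv_name!r}")
    ptvs = {o: cohort.volume(o, ptv_name) for o in have}
    results = []
    for name, level in levels.levels.items():
        fracs = {o: overlap_fraction(level, ptvs[o]) for o in have}
        incl = {o: is_included(f, threshold) for o, f in fracs.items()}
        results.append(
            LevelInclusionResult(
                level_name=name,
                fractions=fracs,
                included=incl,
                count=sum(incl.values()),
                n_observers=len(have),
            )
        )
    return results
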