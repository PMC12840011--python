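"""Table emission and run orchestration.

Produces the three report tables of a cohort analysis as pandas DataFrames
with deterministic ordering and rounding:

* **metrics** — one row per structure with N, mean/SD/range of the observer
  volumes (cm³, 3 significant figures), CoV (2 decimals), CIpairs, mean
  pairwise DSC and mean pairwise MASD; rows sorted from most to least
  variable by CoV, ties alphabetically.  Statistics that are undefined for
  a single observer (CoV, CIpairs, DSC, MASD) are left blank, not zero.
* **levels** — one row per nodal level with the per-observer overlap
  fractions, the inclusion count under the strict >70% rule, and the
  covered-by-all / covered-by-none flags.
* **landmarks** — per-observer craniocaudal borders of a structure, signed
  offsets to the cranial/caudal landmarks, axial widths at the named
  reference slices, plus cohort spread (max pairwise difference) and mean
  rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import pairwise_agreement, round_half_away, round_sig, volume_stats
from .contours import ObserverCohort, read_alias_table, read_contours
from .errors import ConfigError
from .landmarks import (
    LandmarkSet,
    axial_width,
    border_offset,
    cohort_spread,
    craniocaudal_extent,
)
from .levels import DEFAULT_THRESHOLD, NodalLevelSet, level_coverage_table

__all__ = [
    "RunConfig",
    "metrics_table",
    "levels_table",
    "landmarks_table",
    "run_metrics",
    "run_levels",
    "run_landmarks",
    "read_levels_file",
    "read_landmarks_file",
]

log = logging.getLogger(__name__)


def metrics_table(cohort: ObserverCohort, with_masd: bool = True) -> pd.DataFrame:
    """Per-structure volume and agreement statistics, most variable first."""
    rows = []
    for name in cohort.structure_names():
        masks = cohort.volumes(name)
        stats = volume_stats(name, [m.volume_cc() for m in masks.values()])
        row = {
            "structure": name,
            "n": stats.n,
            "mean_cc": round_sig(stats.mean),
            "sd_cc": round_sig(stats.sd),
            "cov": round_half_away(stats.cov, 2),
            "min_cc": round_sig(stats.vmin),
            "max_cc": round_sig(stats.vmax),
            "ci_pairs": np.nan,
            "dsc_mean": np.nan,
            "masd_mean_mm": np.nan,
        }
        if stats.n >= 2:
            if with_masd:
                pa = pairwise_agreement(name, masks)
                s = pa.summary()
                row["masd_mean_mm"] = round_half_away(s["masd_mean_mm"], 2)
            else:
                from .agreement import ci_pairs as _ci, dice as _dice

                vols = list(masks.values())
                pair_d = [
                    _dice(vols[i], vols[j])
                    for i in range(len(vols))
                    for j in range(i + 1, len(vols))
                ]
                s = {"ci_pairs": _ci(vols), "dsc_mean": float(np.mean(pair_d))}
            row["ci_pairs"] = round_half_away(s["ci_pairs"], 2)
            row["dsc_mean"] = round_half_away(s["dsc_mean"], 2)
        else:
            log.warning("structure %r delineated by a single observer; "
                        "CoV/CIpairs/DSC/MASD left blank", name)
            row["cov"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["cov", "structure"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return df


def levels_table(
    cohort: ObserverCohort,
    levels: NodalLevelSet,
    ptv_name: str = "PTV1",
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    results = level_coverage_table(cohort, levels, ptv_name, threshold)
    rows = []
    for r in results:
        row = {
            "level": r.level_name,
            "n_included": r.count,
            "n_observers": r.n_observers,
            "covered_by_all": r.covered_by_all,
            "covered_by_none": r.covered_by_none,
        }
        for o, f in r.fractions.items():
            row[f"frac_{o}"] = round_half_away(f, 3)
        rows.append(row)
    return pd.DataFrame(rows)


def landmarks_table(
    cohort: ObserverCohort,
    landmarks: LandmarkSet,
    structure: str = "PTV1",
    cranial_landmark: str | None = None,
    caudal_landmark: str | None = None,
    width_axis: str = "x",
) -> pd.DataFrame:
    """Border/width report with cohort spread and mean summary rows."""
    observers = cohort.observers_with(structure)
    if not observers:
        raise ConfigError(f"no observer delineated {structure!r}")
    cols: dict[str, list[float]] = {}
    rows = []
    for o in observers:
        vol = cohort.volume(o, structure)
        caudal, cranial = craniocaudal_extent(vol)
        row: dict[str, object] = {
            "observer": o,
            "cranial_extent_mm": cranial,
            "caudal_extent_mm": caudal,
        }
        if cranial_landmark is not None:
            row["cranial_offset_below_mm"] = border_offset(
                cranial, landmarks.z(cranial_landmark), "below"
            )
        if caudal_landmark is not None:
            row["caudal_offset_above_mm"] = border_offset(
                caudal, landmarks.z(caudal_landmark), "above"
            )
        for label, z in landmarks.reference_slices.items():
            row[f"width_{label}_cm"] = round_half_away(axial_width(vol, z, width_axis), 1)
        rows.append(row)
        for k, v in row.items():
            if k != "observer":
                cols.setdefault(k, []).append(float(v))  # type: ignore[arg-type]
    for stat_name, idx in (("cohort_spread", 0), ("cohort_mean", 1)):
        srow: dict[str, object] = {"observer": stat_name}
        for k, vals in cols.items():
            srow[k] = round_half_away(cohort_spread(vals)[idx], 2)
        rows.append(srow)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-driven runs


@dataclass
class RunConfig:
    """Resolved configuration of a report run (paths, names, thresholds)."""

    cohort: str
    dialect: str = "json"
    alias: str | None = None
    levels: str | None = None
    landmarks: str | None = None
    ptv_name: str = "PTV1"
    threshold: float = DEFAULT_THRESHOLD
    out: str = "."
    width_axis: str = "x"
    cranial_landmark: str | None = None
    caudal_landmark: str | None = None
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError(f"threshold must lie in (0, 1), got {self.threshold}")

    def load_cohort(self) -> ObserverCohort:
        alias = read_alias_table(self.alias) if self.alias else None
        return read_contours(self.cohort, dialect=self.dialect, alias=alias)


def read_levels_file(path: str | Path, cohort: ObserverCohort) -> NodalLevelSet:
    """Read nodal-level masks from a JSON-dialect file (all structures of
    all observers in the file become levels) or a directory of NIfTI masks
    named ``<level>.nii(.gz)``."""
    from .contours import read_mask_nifti

    path = Path(path)
    if path.is_dir():
        masks = {}
        for f in sorted(path.glob("*.nii*")):
            name = f.name.removesuffix(".gz").removesuffix(".nii")
            masks[name] = read_mask_nifti(f, cohort.grid)
        if not masks:
            raise ConfigError(f"no NIfTI level masks under {path}")
        return NodalLevelSet(masks)
    lev_cohort = read_contours(path, dialect="json")
    masks = {
        name: lev_cohort.volume(obs, name) for (obs, name) in lev_cohort.structures
    }
    return NodalLevelSet(masks)


def read_landmarks_file(path: str | Path) -> tuple[LandmarkSet, str | None, str | None]:
    """Landmark JSON: either a flat ``{name: z_mm}`` mapping or a structured
    object with ``landmarks``, optional ``reference_slices`` and optional
    ``cranial``/``caudal`` landmark designations."""
    doc = json.loads(Path(path).read_text())
    if "landmarks" in doc:
        return (
            LandmarkSet(dict(doc["landmarks"]), dict(doc.get("reference_slices", {}))),
            doc.get("cranial"),
            doc.get("caudal"),
        )
    return LandmarkSet({k: float(v) for k, v in doc.items()}), None, None


def _write(df: pd.DataFrame, out: str | Path, name: str) -> Path:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    dest = out / name
    df.to_csv(dest, index=False, na_rep="")
    return dest


def run_metrics(config: RunConfig) -> Path:
    cohort = config.load_cohort()
    shared = [s for s in cohort.structure_names() if cohort.n(s) >= 2]
    if not shared:
        raise ConfigError("no structure is shared by at least 2 observers")
    return _write(metrics_table(cohort), config.out, "metrics.csv")


def run_levels(config: RunConfig) -> Path:
    if config.levels is None:
        raise ConfigError("a levels file is required for the levels report")
    cohort = config.load_cohort()
    levels = read_levels_file(config.levels, cohort)
    df = levels_table(cohort, levels, config.ptv_name, config.threshold)
    return _write(df, config.out, "levels.csv")


def run_landmarks(config: RunConfig) -> Path:
    if config.landmarks is None:
        raise ConfigError("a landmarks file is required for the landmarks report")
    cohort = config.load_cohort()
    lset, cranial, caudal = read_landmarks_file(config.landmarks)
    df = landmarks_table(
        cohort,
        lset,
        structure=config.ptv_name,
        cranial_landmark=config.cranial_landmark or cranial,
        caudal_landmark=config.caudal_landmark or caudal,
        width_axis=config.width_axis,
    )
    return _write(df, config.out, "landmarks.csv")
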