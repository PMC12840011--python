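#!/usr/bin/env python
"""Generate the synthetic ten-observer delineation cohort.

The study's original structure sets are not public, so every downstream
analysis runs on a synthetic stand-in with known ground truth: ten observers
contouring two target volumes and sixteen organs at risk on a 1×1×4 mm
planning-CT grid (512×512×80 voxels), with per-observer systematic margins,
smooth boundary noise, caudal PTV1 truncation spanning 20 mm, and realistic
structure omissions (pituitary 7/10, optic chiasm 9/10, TMJs 8/10).

Writes the cohort, level masks, landmarks and ground truth as JSON under
scratch/ (regenerable; later drivers rebuild the cohort from the same seed
if scratch/ is absent).
"""

import json
from dataclasses import asdict
from pathlib import Path

from iovkit import generate, write_contours
from iovkit.synthetic import levels_as_cohort, study_cohort_spec

SEED = 42
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    spec = study_cohort_spec(SEED)
    cohort, truth = generate(spec)
    SCRATCH.mkdir(exist_ok=True)
    write_contours(cohort, SCRATCH / "cohort.json")
    write_contours(levels_as_cohort(spec), SCRATCH / "levels.json")
    (SCRATCH / "landmarks.json").write_text(json.dumps({
        "landmarks": spec.landmarks,
        "reference_slices": spec.reference_slices,
        "cranial": "sphenoid_sinus_floor",
        "caudal": "sternoclavicular_joint",
    }, indent=1))
    (SCRATCH / "ground_truth.json").write_text(json.dumps({
        "shapes": {k: asdict(v) for k, v in truth.shapes.items()},
        "analytic_volumes_cc": truth.analytic_volumes_cc,
        "observers": {k: asdict(v) for k, v in truth.observers.items()},
    }, indent=1))

    n_structs = len({name for _, name in cohort.structures})
    print(f"generated cohort: {len(cohort.observers)} observers, "
          f"{n_structs} structures, grid {spec.grid.size} at {spec.grid.spacing} mm")
    for oid, ot in truth.observers.items():
        omit = f", omitted {list(ot.omitted)}" if ot.omitted else ""
        print(f"  {oid}: margin {ot.margin_mm:+.2f} mm, "
              f"caudal cut z={ot.truncation_z:.0f} mm{omit}")
    print(f"wrote cohort/levels/landmarks/ground truth JSON to {SCRATCH}/")


if __name__ == "__main__":
    main()
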