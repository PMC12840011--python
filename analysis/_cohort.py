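"""Shared loader for the analysis drivers: reuse the simulated cohort from
scratch/ when present, otherwise regenerate it deterministically from the
same seed."""

from pathlib import Path

from iovkit import ObserverCohort, generate, read_contours
from iovkit.synthetic import CohortSpec, study_cohort_spec

SEED = 42
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def load_spec_and_cohort() -> tuple[CohortSpec, ObserverCohort]:
    spec = study_cohort_spec(SEED)
    cohort_path = SCRATCH / "cohort.json"
    if cohort_path.exists():
        return spec, read_contours(cohort_path, dialect="json")
    cohort, _ = generate(spec)
    return spec, cohort
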