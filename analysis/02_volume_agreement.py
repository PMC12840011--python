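#!/usr/bin/env python
"""Per-structure volume statistics and spatial agreement.

For every structure: observer count N, mean/SD/range of the delineated
volumes (cm³), CoV = SD/mean, the pairwise conformity index CIpairs, the
mean pairwise Dice coefficient, and the mean pairwise MASD (mm), sorted
from most to least variable.  Writes results/volume_agreement.csv.
"""

from _cohort import RESULTS, load_spec_and_cohort
from iovkit.report import metrics_table


def main() -> None:
    _, cohort = load_spec_and_cohort()
    df = metrics_table(cohort)
    RESULTS.mkdir(exist_ok=True)
    dest = RESULTS / "volume_agreement.csv"
    df.to_csv(dest, index=False, na_rep="")
    print(df.to_string(index=False))
    top, bottom = df.iloc[0], df.iloc[len(df) - 1]
    print(f"\nmost variable: {top['structure']} (CoV {top['cov']}), "
          f"least variable: {bottom['structure']} (CoV {bottom['cov']})")
    ptv = df.set_index("structure")
    print(f"PTV1 CIpairs {ptv.loc['PTV1', 'ci_pairs']}, "
          f"PTV2 CIpairs {ptv.loc['PTV2', 'ci_pairs']}")
    print(f"wrote {dest}")


if __name__ == "__main__":
    main()
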