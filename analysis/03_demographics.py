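"""Group-comparison table for cohort demographics.

Reproduces the study-style table (t-tests for age/education/MMSE,
chi-square for sex) on a cohort manifest, and prints the reference
computation from the study's printed summaries.

    python analysis/03_demographics.py --manifest results/cohort/manifest.csv
"""

import argparse
from pathlib import Path

from hipporad.cohort_stats import (chi_square_2x2, demographics_table,
                                   student_t_from_summary)
from hipporad.io import read_manifest


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--manifest", type=Path,
                    default=Path("results/cohort/manifest.csv"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/demographics.csv"))
    args = ap.parse_args()

    manifest = read_manifest(args.manifest)
    table = demographics_table(manifest)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(table.to_string(index=False))
    print(f"-> {args.out}")

    print("\nreference: statistics from the printed 42-vs-44 summaries")
    t, _, p = student_t_from_summary(64.17, 10.57, 42, 65.43, 9.70, 44)
    print(f"  age:       t = {t:.2f}, p = {p:.2f}")
    t, _, p = student_t_from_summary(7.74, 2.84, 42, 7.09, 3.38, 44)
    print(f"  education: t = {t:.2f}, p = {p:.2f}")
    chi2, _, p = chi_square_2x2(18, 24, 20, 24)
    print(f"  sex:       chi2 = {chi2:.2f}, p = {p:.2f}")


if __name__ == "__main__":
    main()
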