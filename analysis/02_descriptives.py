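"""Descriptive (Table-1 style) analysis.

Two parts. First, the exact reproduction: prevalence ratios, odds ratios
and marginal percentages recomputed from the published survey counts —
these should match the printed values (stillbirth PR 2.40, 95% CI 2.21-2.62;
preterm PR 0.47; unclean prevalence 89.3%; ...). Second, the same report
generated from a cohort CSV (synthetic or otherwise), written to --out.

Usage: python analysis/02_descriptives.py --cohort results/sim/cohort.csv \
           --out results/descriptives
"""

import argparse
from pathlib import Path

from hapstar.descriptives import table1_report
from hapstar.synthetic import read_cohort_csv
from hapstar.table1 import published_descriptives


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=None,
                    help="cohort CSV; omit to only print the published check")
    ap.add_argument("--out", type=Path, default=Path("results/descriptives"))
    args = ap.parse_args()

    print("published counts, recomputed:")
    d = published_descriptives()
    print(f"  stillbirth PR {d['stillbirth_pr']:.2f} "
          f"({d['stillbirth_pr_ci_low']:.2f}, {d['stillbirth_pr_ci_high']:.2f})")
    print(f"  LBW PR        {d['lbw_pr']:.2f} "
          f"({d['lbw_pr_ci_low']:.2f}, {d['lbw_pr_ci_high']:.2f})")
    print(f"  preterm PR    {d['preterm_pr']:.2f} "
          f"({d['preterm_pr_ci_low']:.2f}, {d['preterm_pr_ci_high']:.2f})")
    print(f"  smoker PR     {d['smoker_pr']:.2f}")
    print(f"  education OR  primary {d['education_primary_or']:.2f}, "
          f"secondary {d['education_secondary_or']:.2f}, "
          f"higher {d['education_higher_or']:.2f}  (ref: no education)")
    print(f"  unclean fuel prevalence      {d['unclean_prevalence_pct']:.1f}%")
    print(f"  stillbirths / pregnancies    {d['stillbirth_pct_of_pregnancies']:.1f}%")
    print(f"  unclean share of stillbirths {d['unclean_pct_among_stillbirths']:.1f}%")
    print(f"  LBW share of weighed births  {d['lbw_pct_of_observed']:.2f}%")

    if args.cohort is not None:
        births = read_cohort_csv(args.cohort)
        args.out.mkdir(parents=True, exist_ok=True)
        table = table1_report(births, args.out / "table1.csv")
        print(f"\ncohort report: {len(table)} rows -> {args.out}/table1.csv")


if __name__ == "__main__":
    main()
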