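#!/usr/bin/env python
"""Descriptive epidemiology of the cohort: demographic/outcome/onset table,
vaccine dose table, and the yearly report series.

Reads the normalized reports from results/cohort/, writes three TSVs under
results/descriptives/, and prints the headline shares (sex split, under-2
share, recovery share, onset-within-30-days share).
"""

import argparse
from pathlib import Path

from dtapsafe.cohort import filter_cohort
from dtapsafe.descriptives import (
    onset_summary,
    seriousness_summary,
    summarize_demographics,
    summarize_vaccines,
    yearly_series,
)
from dtapsafe.vaers_io import read_reports

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--reports", type=Path,
                        default=ROOT / "results" / "cohort" / "normalized_reports.tsv")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "descriptives")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = filter_cohort(read_reports(args.reports))
    demo = summarize_demographics(cohort)
    demo.to_csv(args.out / "table1_demographics.tsv", sep="\t", index=False)
    seriousness_summary(cohort).to_csv(args.out / "seriousness.tsv", sep="\t", index=False)
    summarize_vaccines(cohort).to_csv(args.out / "table2_vaccines.tsv", sep="\t", index=False)
    yearly_series(cohort).to_csv(args.out / "yearly_series.tsv", sep="\t", index=False)

    def share(section, level):
        row = demo[(demo.section == section) & (demo.level == level)]
        return f"{row['count'].iloc[0]} ({row['percent'].iloc[0]}%)"

    onset = onset_summary(cohort)
    print(f"cohort size: {len(cohort)}")
    print(f"male {share('gender', 'Male')}, female {share('gender', 'Female')}")
    print(f"under 2 years: {share('age_stratum', '<2')}")
    print(f"recovered: {share('primary_outcome', 'Recovered')}")
    print(f"onset < 30 days: {share('onset_days', '<30')}")
    print(
        f"onset days: mean {onset.mean:.1f} (sd {onset.sd:.0f}), "
        f"median {onset.median:.2f} (range {onset.min:.0f}-{onset.max:.0f}); "
        f"<=1 day: {onset.n_within_1_day} ({onset.share_within_1_day}%)"
    )


if __name__ == "__main__":
    main()
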