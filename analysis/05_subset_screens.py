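#!/usr/bin/env python
"""Dedicated subset analyses: serious-only and fatal-only disproportionality
runs (outcome-matched backgrounds), the Designated Medical Event screen, and
the SIDS vaccination-to-death interval table.

Writes under results/screens/ and prints each subset's flagged PTs, the DME
screen summary, and the SIDS interval distribution.
"""

import argparse
import warnings
from pathlib import Path

from dtapsafe.cohort import filter_cohort
from dtapsafe.descriptives import sids_interval_table
from dtapsafe.disprop import analyze, build_tables
from dtapsafe.screening import dme_screen, subset_signal_run
from dtapsafe.synthetic import toy_dme_list
from dtapsafe.vaers_io import DTAP_BRANDS, read_reports

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--reports", type=Path,
                        default=ROOT / "results" / "cohort" / "normalized_reports.tsv")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "screens")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    reports = read_reports(args.reports)
    cohort = filter_cohort(reports)
    background = [
        r for r in reports
        if not any(v.brand_label in DTAP_BRANDS for v in r.vaccines)
        and r.age_years is not None and 0 <= r.age_years < 7
    ]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for subset in ("serious", "fatal"):
            results = subset_signal_run(cohort, background, subset)
            results.to_csv(args.out / f"signals_pt_{subset}.tsv", sep="\t", index=False)
            flagged = results[results.positive_any]
            print(f"{subset} subset: {int((results.a + results.b).iloc[0])} reports, "
                  f"{len(flagged)} flagged PTs: {sorted(flagged.event_label)}")

        pt_results = analyze(build_tables(cohort, background, level="PT"))

    kept, summary = dme_screen(pt_results, toy_dme_list())
    kept.to_csv(args.out / "dme_screen.tsv", sep="\t", index=False)
    print(
        f"DME screen: {summary['n_matched']} of {summary['n_dme_pts']} DME PTs "
        f"observed, {summary['n_positive']} flagged positive"
    )

    sids = sids_interval_table(cohort)
    sids.to_csv(args.out / "sids_intervals.tsv", sep="\t", index=False)
    total = sids["count"].sum()
    print(f"SIDS cases: {total}; interval distribution:")
    for _, row in sids.iterrows():
        mean = "-" if row.bin == "NA" else f"{row.mean_interval_days:.2f}"
        print(f"  {row.bin}: {row['count']} ({row.percent}%), mean {mean} days")


if __name__ == "__main__":
    main()
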