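#!/usr/bin/env python
"""Ingest the triple, deduplicate, and apply the study eligibility filters.

Reads results/synthetic/ (run 01 first), writes the normalized report file
and the exclusion log under results/cohort/, and prints the accounting:
every distinct raw report id ends up kept, excluded, or removed.
"""

import argparse
from pathlib import Path

import pandas as pd

from dtapsafe.cohort import filter_cohort
from dtapsafe.vaers_io import assemble_reports, deduplicate, read_triple, write_reports

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--triple", type=Path, default=ROOT / "results" / "synthetic")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "cohort")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    triple = read_triple(
        args.triple / "data.csv", args.triple / "vax.csv", args.triple / "symptoms.csv"
    )
    n_ids = triple.data_rows["VAERS_ID"].nunique()
    reports, assemble_exclusions = assemble_reports(triple)
    reports, n_removed = deduplicate(reports)
    cohort = filter_cohort(reports)

    write_reports(reports, args.out / "normalized_reports.tsv")
    rows = (
        [{"stage": "assemble", "reason": k, "count": v} for k, v in assemble_exclusions.items()]
        + [{"stage": "dedup", "reason": "duplicate_report", "count": n_removed}]
        + [{"stage": "filter", "reason": k, "count": v} for k, v in cohort.exclusions.items()]
    )
    pd.DataFrame(rows).to_csv(args.out / "exclusions.tsv", sep="\t", index=False)

    print(f"raw distinct ids: {n_ids}")
    print(f"normalized reports: {len(reports)} (removed {n_removed} duplicates)")
    print(f"cohort: {len(cohort)} eligible reports; exclusions: {cohort.exclusions}")
    print(f"negative-onset anomalies: {cohort.n_negative_onset}")


if __name__ == "__main__":
    main()
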