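"""Descriptive epidemiology tables: demographic/outcome frequencies, vaccine
dose characteristics, yearly report series, onset-time summaries, and the
SIDS vaccination-to-death interval table.

All frequency tables are long-format DataFrames with columns
(section, level, count, percent, denominator); ``percent`` is
100*count/denominator rounded half-up to two decimals, matching the printed
style of published VAERS analyses.  Report-level tables use the number of
reports as the denominator; the vaccine table uses the number of administered
(whitelisted) doses, which can exceed the report count.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cohort import AGE_STRATA, Cohort
from .vaers_io import DTAP_BRANDS

FREQ_COLUMNS = ["section", "level", "count", "percent", "denominator"]

ONSET_BINS: tuple[str, ...] = (
    "<30", "≥30 and <60", "≥60 and <90", "≥90 and <120", "≥120 and <150",
    "≥150 and <180", "≥180 and <360", "≥360", "N/A",
)

SIDS_BINS: tuple[str, ...] = ("0–6", "7–13", "14–20", "21–28", "≥29", "NA")

OUTCOME_LEVELS: tuple[str, ...] = (
    "Died", "Disability", "Hospitalized", "Life threatening",
    "Prolonged hospitalization", "Recovered", "N/A",
)

#: VAX_NAME label -> display name used in the vaccine table.
BRAND_DISPLAY = {
    "DTAP (ACEL-IMUNE)": "Acel-Imune",
    "DTAP (CERTIVA)": "Certiva",
    "DTAP (DAPTACEL)": "Daptacel",
    "DTAP (INFANRIX)": "Infanrix",
    "DTAP (TRIPEDIA)": "Tripedia",
    "DTAP (NO BRAND NAME)": "No Brand Name",
}

DOSE_LEVELS: tuple[str, ...] = ("1", "2", "3", "4", "5", "6", "7+", "N/A")


def percent(count: int, denominator: int) -> float:
    """100*count/denominator rounded half-up to 2 decimals; nan if denom 0."""
    if denominator == 0:
        return float("nan")
    frac = Decimal(count) * Decimal(100) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_percent(count: int, denominator: int) -> str:
    """Printed-style percent; nonzero counts rounding to 0.00 show "<0.01%"."""
    p = percent(count, denominator)
    if count > 0 and p < 0.01:
        return "<0.01%"
    return f"{p:.2f}%"


def _freq_section(section: str, counts: dict[str, int], denominator: int) -> pd.DataFrame:
    rows = [
        {
            "section": section,
            "level": level,
            "count": n,
            "percent": percent(n, denominator),
            "denominator": denominator,
        }
        for level, n in counts.items()
    ]
    return pd.DataFrame(rows, columns=FREQ_COLUMNS)


def bin_onset_days(days: float) -> str:
    """Half-open onset-day bins matching the demographic table layout."""
    if days is None or (isinstance(days, float) and np.isnan(days)):
        return "N/A"
    edges = [(30, "<30"), (60, "≥30 and <60"), (90, "≥60 and <90"),
             (120, "≥90 and <120"), (150, "≥120 and <150"),
             (180, "≥150 and <180"), (360, "≥180 and <360")]
    for hi, label in edges:
        if days < hi:
            return label
    return "≥360"


def summarize_demographics(cohort: Cohort) -> pd.DataFrame:
    """Gender / age stratum / primary outcome / onset-bin frequency table."""
    f = cohort.frame
    n = len(f)
    sections = []

    sex_display = {"female": "Female", "male": "Male", "unknown": "N/A"}
    sex_counts = f["sex"].map(sex_display).value_counts()
    sections.append(_freq_section(
        "gender", {lab: int(sex_counts.get(lab, 0)) for lab in ("Female", "Male", "N/A")}, n
    ))

    age_counts = f["age_stratum"].value_counts()
    sections.append(_freq_section(
        "age_stratum", {lab: int(age_counts.get(lab, 0)) for lab in AGE_STRATA}, n
    ))

    out_counts = f["primary_outcome"].value_counts()
    sections.append(_freq_section(
        "primary_outcome", {lab: int(out_counts.get(lab, 0)) for lab in OUTCOME_LEVELS}, n
    ))

    onset_bins = f["onset_days"].map(bin_onset_days)
    bin_counts = onset_bins.value_counts()
    sections.append(_freq_section(
        "onset_days", {lab: int(bin_counts.get(lab, 0)) for lab in ONSET_BINS}, n
    ))

    return pd.concat(sections, ignore_index=True)


def seriousness_summary(cohort: Cohort) -> pd.DataFrame:
    """Serious / non-serious and fatal / non-fatal report shares."""
    f = cohort.frame
    n = len(f)
    serious = int(f["serious"].sum())
    fatal = int(f["fatal"].sum())
    return pd.concat(
        [
            _freq_section("seriousness", {"Serious": serious, "Non-serious": n - serious}, n),
            _freq_section("fatality", {"Fatal": fatal, "Non-fatal": n - fatal}, n),
        ],
        ignore_index=True,
    )


@dataclass
class OnsetSummary:
    """Binned onset-time table plus moments of the non-missing intervals."""

    table: pd.DataFrame
    mean: float
    sd: float
    median: float
    min: float
    max: float
    n_within_1_day: int
    share_within_1_day: float  # percent of all reports with onset <= 1 day


def onset_summary(cohort: Cohort) -> OnsetSummary:
    f = cohort.frame
    n = len(f)
    days = f["onset_days"].dropna()
    bins = f["onset_days"].map(bin_onset_days)
    counts = bins.value_counts()
    table = _freq_section(
        "onset_days", {lab: int(counts.get(lab, 0)) for lab in ONSET_BINS}, n
    )
    n_leq1 = int((days <= 1).sum())
    empty = len(days) == 0
    return OnsetSummary(
        table=table,
        mean=float("nan") if empty else float(days.mean()),
        sd=float("nan") if len(days) < 2 else float(days.std(ddof=1)),
        median=float("nan") if empty else float(days.median()),
        min=float("nan") if empty else float(days.min()),
        max=float("nan") if empty else float(days.max()),
        n_within_1_day=n_leq1,
        share_within_1_day=percent(n_leq1, n),
    )


def summarize_vaccines(
    cohort: Cohort, whitelist: frozenset[str] | tuple[str, ...] = DTAP_BRANDS
) -> pd.DataFrame:
    """Brand / manufacturer / dose-in-series table over whitelisted doses.

    The denominator is the number of administered whitelisted vaccine entries
    (doses), not reports: one report may carry more than one DTaP entry.
    """
    whitelist = frozenset(whitelist)
    entries = [
        v for r in cohort.reports for v in r.vaccines if v.brand_label in whitelist
    ]
    n = len(entries)

    brand_counts: dict[str, int] = {BRAND_DISPLAY.get(b, b): 0 for b in sorted(whitelist)}
    manu_counts: dict[str, int] = {}
    dose_counts: dict[str, int] = {lab: 0 for lab in DOSE_LEVELS}
    for v in entries:
        brand_counts[BRAND_DISPLAY.get(v.brand_label, v.brand_label)] += 1
        manu = v.manufacturer if v.manufacturer else "N/A"
        manu_counts[manu] = manu_counts.get(manu, 0) + 1
        dose = v.dose_series if v.dose_series in DOSE_LEVELS else "N/A"
        dose_counts[dose] += 1

    manu_counts = dict(sorted(manu_counts.items()))
    return pd.concat(
        [
            _freq_section("vaccine_name", brand_counts, n),
            _freq_section("manufacturer", manu_counts, n),
            _freq_section("dose_series", dose_counts, n),
        ],
        ignore_index=True,
    )


def yearly_series(cohort: Cohort, whitelist=DTAP_BRANDS) -> pd.DataFrame:
    """Dense (year, brand, n_reports) grid; one count per report-brand pair."""
    whitelist = frozenset(whitelist)
    rows = []
    for r in cohort.reports:
        year = r.received_year
        if year is None:
            continue
        brands = {v.brand_label for v in r.vaccines if v.brand_label in whitelist}
        for b in brands:
            rows.append((year, BRAND_DISPLAY.get(b, b)))
    if not rows:
        return pd.DataFrame(columns=["year", "brand", "n_reports"])
    df = pd.DataFrame(rows, columns=["year", "brand"])
    counts = df.value_counts().rename("n_reports").reset_index()
    years = range(int(df["year"].min()), int(df["year"].max()) + 1)
    brands = sorted(df["brand"].unique())
    grid = pd.MultiIndex.from_product([years, brands], names=["year", "brand"]).to_frame(
        index=False
    )
    out = grid.merge(counts, on=["year", "brand"], how="left").fillna({"n_reports": 0})
    out["n_reports"] = out["n_reports"].astype(int)
    return out


def bin_sids_interval(days: float) -> str:
    if days is None or (isinstance(days, float) and np.isnan(days)):
        return "NA"
    if days <= 6:
        return "0–6"
    if days <= 13:
        return "7–13"
    if days <= 20:
        return "14–20"
    if days <= 28:
        return "21–28"
    return "≥29"


def sids_interval_table(
    cohort: Cohort, sids_pt_label: str = "Sudden infant death syndrome"
) -> pd.DataFrame:
    """Fatal SIDS cases binned by vaccination-to-onset interval.

    Restricts to fatal reports whose PT set contains ``sids_pt_label``; for
    each interval bin gives the case count, percent of all SIDS cases, and
    mean in-bin interval (the NA bin has no mean).
    """
    fatal = cohort.frame["fatal"].to_numpy()
    idx = [
        i for i, r in enumerate(cohort.reports)
        if fatal[i] and sids_pt_label in r.pts
    ]
    days = cohort.frame["onset_days"].iloc[idx]
    total = len(idx)
    bins = days.map(bin_sids_interval)
    rows = []
    for lab in SIDS_BINS:
        in_bin = days[bins == lab]
        count = len(in_bin)
        mean = float(in_bin.mean()) if lab != "NA" and count else float("nan")
        rows.append(
            {
                "bin": lab,
                "count": count,
                "percent": percent(count, total),
                "mean_interval_days": mean,
            }
        )
    return pd.DataFrame(rows, columns=["bin", "count", "percent", "mean_interval_days"])
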