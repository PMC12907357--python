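"""Study eligibility filters and derived analysis variables.

The analysis cohort is: deduplicated reports received between 1990-01-01 and
2025-05-31 for children under 7 years with at least one DTaP vaccine entry.
Per-report derived variables are the age stratum (<2, >=2 and <5, >=5 and <7
years), the vaccination-to-onset interval in days, regulatory seriousness
(death, life-threatening event, hospitalization or its prolongation, or
disability), fatality, and a single primary clinical outcome label chosen by
a severity-ordered precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

import pandas as pd

from .vaers_io import DTAP_BRANDS, Report

AGE_STRATA: tuple[str, ...] = ("<2", "≥2 and <5", "≥5 and <7")

#: Outcome-flag precedence (most severe first) -> primary outcome label.
DEFAULT_OUTCOME_PRECEDENCE: tuple[tuple[str, str], ...] = (
    ("died", "Died"),
    ("life_threatening", "Life threatening"),
    ("prolonged_hospitalization", "Prolonged hospitalization"),
    ("hospitalized", "Hospitalized"),
    ("disability", "Disability"),
    ("recovered", "Recovered"),
)

SERIOUS_FLAGS = frozenset(
    {"died", "life_threatening", "hospitalized", "prolonged_hospitalization", "disability"}
)


@dataclass(frozen=True)
class CohortCriteria:
    """Eligibility criteria: age cut-off, brand whitelist, received-date window."""

    max_age_years_exclusive: float = 7.0
    brand_whitelist: frozenset[str] = frozenset(DTAP_BRANDS)
    window: tuple[date, date] = (date(1990, 1, 1), date(2025, 5, 31))

    def __post_init__(self) -> None:
        if self.window[0] > self.window[1]:
            raise ValueError("window start must be <= window end")
        if not self.brand_whitelist:
            raise ValueError("brand whitelist must be non-empty")


@dataclass
class Cohort:
    """Eligible reports plus their derived variables (1:1 aligned frame)."""

    reports: list[Report]
    frame: pd.DataFrame
    exclusions: dict[str, int] = field(default_factory=dict)
    n_negative_onset: int = 0

    def __len__(self) -> int:
        return len(self.reports)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, reports: list[Report] | None = None) -> "Cohort":
        """Build a cohort directly from a derived-variable frame (tests, fixtures)."""
        return cls(reports=reports if reports is not None else [], frame=frame)


def assign_age_stratum(age_years: float) -> str:
    """Half-open age bins: [0,2) -> "<2", [2,5), [5,7)."""
    if age_years < 0 or age_years >= 7:
        raise ValueError(f"age {age_years} outside [0, 7)")
    if age_years < 2:
        return AGE_STRATA[0]
    if age_years < 5:
        return AGE_STRATA[1]
    return AGE_STRATA[2]


def compute_onset_days(
    vaccination_date: date | None, onset_date: date | None
) -> tuple[int | None, bool]:
    """Calendar days from vaccination to onset.

    Returns ``(days, anomaly)``: either date missing -> ``(None, False)``;
    onset before vaccination -> ``(None, True)`` (logged anomaly, the interval
    cannot be negative in a valid report).
    """
    if vaccination_date is None or onset_date is None:
        return None, False
    delta = (onset_date - vaccination_date).days
    if delta < 0:
        return None, True
    return delta, False


def classify_seriousness(outcome_flags: Iterable[str]) -> tuple[bool, bool]:
    """(serious, fatal) per the regulatory seriousness definition."""
    flags = set(outcome_flags)
    return bool(flags & SERIOUS_FLAGS), "died" in flags


def primary_outcome(
    outcome_flags: Iterable[str],
    precedence: Sequence[tuple[str, str]] = DEFAULT_OUTCOME_PRECEDENCE,
) -> str:
    """Single outcome label by severity precedence; no flags -> "N/A"."""
    flags = set(outcome_flags)
    for flag, label in precedence:
        if flag in flags:
            return label
    return "N/A"


def derive_frame(reports: Sequence[Report]) -> tuple[pd.DataFrame, int]:
    """Per-report derived variables; returns (frame, n_negative_onset)."""
    rows = []
    n_anomalies = 0
    for r in reports:
        onset_days, anomaly = compute_onset_days(r.vaccination_date, r.onset_date)
        n_anomalies += anomaly
        serious, fatal = classify_seriousness(r.outcome_flags)
        rows.append(
            {
                "report_id": r.report_id,
                "received_year": r.received_year,
                "age_years": r.age_years,
                "age_stratum": assign_age_stratum(r.age_years),
                "sex": r.sex,
                "onset_days": float("nan") if onset_days is None else float(onset_days),
                "serious": serious,
                "fatal": fatal,
                "primary_outcome": primary_outcome(r.outcome_flags),
            }
        )
    columns = [
        "report_id", "received_year", "age_years", "age_stratum", "sex",
        "onset_days", "serious", "fatal", "primary_outcome",
    ]
    return pd.DataFrame(rows, columns=columns), n_anomalies


def filter_cohort(reports: Sequence[Report], criteria: CohortCriteria | None = None) -> Cohort:
    """Apply eligibility filters and derive analysis variables.

    Exclusion reasons are tallied in order: missing age, age at/over the
    cut-off, no whitelisted vaccine entry, missing received date, received
    date outside the study window.
    """
    criteria = criteria or CohortCriteria()
    kept: list[Report] = []
    exclusions = {
        "age_missing": 0,
        "age_out_of_range": 0,
        "no_whitelisted_vaccine": 0,
        "received_date_missing": 0,
        "outside_window": 0,
    }
    lo, hi = criteria.window
    for r in reports:
        if r.age_years is None:
            exclusions["age_missing"] += 1
            continue
        if not (0 <= r.age_years < criteria.max_age_years_exclusive):
            exclusions["age_out_of_range"] += 1
            continue
        if not any(v.brand_label in criteria.brand_whitelist for v in r.vaccines):
            exclusions["no_whitelisted_vaccine"] += 1
            continue
        if r.received_date is None:
            exclusions["received_date_missing"] += 1
            continue
        if not (lo <= r.received_date <= hi):
            exclusions["outside_window"] += 1
            continue
        kept.append(r)
    if not kept:
        warnings.warn("cohort is empty after filtering", stacklevel=2)
    frame, n_anomalies = derive_frame(kept)
    return Cohort(reports=kept, frame=frame, exclusions=exclusions,
                  n_negative_onset=n_anomalies)
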