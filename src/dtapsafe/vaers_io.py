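"""Reading, normalising and writing spontaneous-report data in the VAERS
public-download layout.

VAERS distributes its data as yearly CSV triples: a report-level DATA file
(demographics, dates, outcome flags), a VAX file with one row per administered
vaccine, and a SYMPTOMS file in which each row carries up to five MedDRA
Preferred Terms (PTs) for a report; reports with more than five coded events
span several symptom rows.  This module parses that layout into normalised
:class:`Report` records, deduplicates them, and loads the two dictionary
inputs the analysis needs: a PT -> System Organ Class (SOC) mapping and a
Designated Medical Event (DME) PT list.  MedDRA itself is licensed, so the
mapping is always user-supplied data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: The six DTaP brand labels as they appear in the VAX_NAME column.
DTAP_BRANDS: tuple[str, ...] = (
    "DTAP (ACEL-IMUNE)",
    "DTAP (CERTIVA)",
    "DTAP (DAPTACEL)",
    "DTAP (INFANRIX)",
    "DTAP (TRIPEDIA)",
    "DTAP (NO BRAND NAME)",
)

#: VAERS outcome columns -> canonical flag names.
OUTCOME_COLUMNS: dict[str, str] = {
    "DIED": "died",
    "L_THREAT": "life_threatening",
    "HOSPITAL": "hospitalized",
    "X_STAY": "prolonged_hospitalization",
    "DISABLE": "disability",
    "RECOVD": "recovered",
}

SEX_CODES = {"F": "female", "M": "male", "U": "unknown", "": "unknown"}

#: Label used when a PT has no entry in the supplied PT->SOC mapping.
UNMAPPED_SOC = "UNMAPPED"

# Legacy header spellings seen in older public files; unknown extras are
# simply ignored downstream.
_COLUMN_ALIASES = {
    "VAERSID": "VAERS_ID",
    "VAX_DOSE": "VAX_DOSE_SERIES",
    "SYMPTOM_1": "SYMPTOM1",
    "SYMPTOM_2": "SYMPTOM2",
    "SYMPTOM_3": "SYMPTOM3",
    "SYMPTOM_4": "SYMPTOM4",
    "SYMPTOM_5": "SYMPTOM5",
}

_DATA_REQUIRED = ["VAERS_ID", "RECVDATE", "AGE_YRS", "SEX", "VAX_DATE", "ONSET_DATE"]
_VAX_REQUIRED = ["VAERS_ID", "VAX_NAME"]
_SYMPTOM_REQUIRED = ["VAERS_ID", "SYMPTOM1"]

_SYMPTOM_SLOTS = ["SYMPTOM1", "SYMPTOM2", "SYMPTOM3", "SYMPTOM4", "SYMPTOM5"]


class VaccineEntry(NamedTuple):
    """One per-vaccine row: brand label, manufacturer, dose-in-series token.

    ``dose_series`` is "1".."6", the literal "7+", or "" when unknown.
    """

    brand_label: str
    manufacturer: str
    dose_series: str


@dataclass(frozen=True)
class Report:
    """One normalised spontaneous report."""

    report_id: str
    received_date: date | None
    age_years: float | None
    sex: str  # female / male / unknown
    vaccination_date: date | None
    onset_date: date | None
    outcome_flags: frozenset[str]
    vaccines: tuple[VaccineEntry, ...]
    pts: frozenset[str]

    @property
    def received_year(self) -> int | None:
        return self.received_date.year if self.received_date is not None else None


@dataclass
class RawTriple:
    """The three VAERS-format tables, as string-typed DataFrames."""

    data_rows: pd.DataFrame
    vax_rows: pd.DataFrame
    symptom_rows: pd.DataFrame


@dataclass
class PtSocMap:
    """Total PT -> SOC lookup; unknown PTs fall into the UNMAPPED bucket."""

    mapping: dict[str, str]

    def get(self, pt: str) -> str:
        return self.mapping.get(pt.strip(), UNMAPPED_SOC)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class DmeList:
    """Ordered, unique list of Designated Medical Event PTs."""

    pts: tuple[str, ...]

    def __contains__(self, pt: str) -> bool:
        return pt.strip() in self._set

    def __len__(self) -> int:
        return len(self.pts)

    def __iter__(self):
        return iter(self.pts)

    def __post_init__(self) -> None:
        self._set = set(self.pts)


def _read_csv(path) -> pd.DataFrame:
    """UTF-8 with latin-1 fallback; everything read as strings, '' = missing."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except UnicodeDecodeError:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="latin-1")
    df.columns = [_COLUMN_ALIASES.get(c.strip().upper(), c.strip().upper()) for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file is missing required column(s): {', '.join(missing)}")


def parse_date_column(series: pd.Series) -> pd.Series:
    """Parse VAERS MM/DD/YYYY dates (ISO accepted too); unparseable -> NaT."""
    s = series.astype(str).str.strip()
    us = pd.to_datetime(s, format="%m/%d/%Y", errors="coerce")
    iso = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
    return us.fillna(iso)


def read_triple(data_path, vax_path, symptoms_path) -> RawTriple:
    """Read the three VAERS-format CSV files.

    Rows are never dropped here: unparseable fields become missing during
    assembly.  A missing file raises ``FileNotFoundError``; a missing required
    column raises ``ValueError`` naming the column.
    """
    data = _read_csv(data_path)
    vax = _read_csv(vax_path)
    symptoms = _read_csv(symptoms_path)
    _require_columns(data, _DATA_REQUIRED, "data")
    _require_columns(vax, _VAX_REQUIRED, "vaccine")
    _require_columns(symptoms, _SYMPTOM_REQUIRED, "symptoms")
    return RawTriple(data_rows=data, vax_rows=vax, symptom_rows=symptoms)


def _to_date(ts) -> date | None:
    return None if pd.isna(ts) else ts.date()


def assemble_reports(raw: RawTriple) -> tuple[list[Report], dict[str, int]]:
    """Normalise a :class:`RawTriple` into one :class:`Report` per report id.

    PTs are unioned across a report's symptom rows; vaccine entries are kept
    in file order.  Returns ``(reports, exclusion_log)``.  Reports without any
    PT are excluded (counted under ``no_symptoms``); ids present only in the
    vaccine/symptom files never form reports (counted under ``orphan_ids``);
    duplicate data-file rows for one id collapse to the first row (counted
    under ``duplicate_data_rows``, not part of report accounting).
    """
    data = raw.data_rows.copy()
    exclusions = {"no_symptoms": 0, "orphan_ids": 0, "duplicate_data_rows": 0}

    n_rows = len(data)
    data["VAERS_ID"] = data["VAERS_ID"].astype(str).str.strip()
    data = data.drop_duplicates(subset="VAERS_ID", keep="first")
    exclusions["duplicate_data_rows"] = n_rows - len(data)

    data_ids = set(data["VAERS_ID"])

    # PT sets per id
    sym = raw.symptom_rows
    sym_ids = sym["VAERS_ID"].astype(str).str.strip().to_numpy()
    pts_by_id: dict[str, set[str]] = {}
    slot_cols = [c for c in _SYMPTOM_SLOTS if c in sym.columns]
    slot_arrays = [sym[c].astype(str).str.strip().to_numpy() for c in slot_cols]
    for i, rid in enumerate(sym_ids):
        pts = pts_by_id.setdefault(rid, set())
        for arr in slot_arrays:
            v = arr[i]
            if v:
                pts.add(v)

    # Vaccine entries per id, in file order
    vax = raw.vax_rows
    vax_ids = vax["VAERS_ID"].astype(str).str.strip().to_numpy()
    brands = vax["VAX_NAME"].astype(str).str.strip().to_numpy()
    manus = (
        vax["VAX_MANU"].astype(str).str.strip().to_numpy()
        if "VAX_MANU" in vax.columns
        else np.full(len(vax), "")
    )
    doses = (
        vax["VAX_DOSE_SERIES"].astype(str).str.strip().to_numpy()
        if "VAX_DOSE_SERIES" in vax.columns
        else np.full(len(vax), "")
    )
    vax_by_id: dict[str, list[VaccineEntry]] = {}
    for i, rid in enumerate(vax_ids):
        dose = doses[i]
        if dose.upper() in {"UNK", "N/A", "NA"}:
            dose = ""
        vax_by_id.setdefault(rid, []).append(
            VaccineEntry(brand_label=brands[i], manufacturer=manus[i], dose_series=dose)
        )

    orphan = (set(pts_by_id) | set(vax_by_id)) - data_ids
    exclusions["orphan_ids"] = len(orphan)

    recv = parse_date_column(data["RECVDATE"]).dt.date.to_numpy()
    vdate = parse_date_column(data["VAX_DATE"]).dt.date.to_numpy()
    odate = parse_date_column(data["ONSET_DATE"]).dt.date.to_numpy()
    ages = pd.to_numeric(data["AGE_YRS"].replace("", None), errors="coerce").to_numpy()
    rids = data["VAERS_ID"].to_numpy()
    sexes = data["SEX"].astype(str).str.strip().str.upper().to_numpy()
    flag_arrays = {
        name: (data[col].astype(str).str.strip().str.upper() == "Y").to_numpy()
        for col, name in OUTCOME_COLUMNS.items()
        if col in data.columns
    }

    reports: list[Report] = []
    for i, rid in enumerate(rids):
        pts = pts_by_id.get(rid, set())
        if not pts:
            exclusions["no_symptoms"] += 1
            continue
        flags = frozenset(name for name, arr in flag_arrays.items() if arr[i])
        age = ages[i]
        reports.append(
            Report(
                report_id=rid,
                received_date=None if pd.isna(recv[i]) else recv[i],
                age_years=None if np.isnan(age) else float(age),
                sex=SEX_CODES.get(sexes[i], "unknown"),
                vaccination_date=None if pd.isna(vdate[i]) else vdate[i],
                onset_date=None if pd.isna(odate[i]) else odate[i],
                outcome_flags=flags,
                vaccines=tuple(vax_by_id.get(rid, [])),
                pts=frozenset(pts),
            )
        )
    return reports, exclusions


def _id_sort_key(report_id: str):
    # numeric ids compare numerically; mixed ids fall back to string order
    return (0, int(report_id), "") if report_id.isdigit() else (1, 0, report_id)


def deduplicate(
    reports: Sequence[Report], use_content_key: bool = False
) -> tuple[list[Report], int]:
    """Collapse duplicate reports; returns ``(kept, n_removed)``.

    The primary key is the report id (first occurrence wins).  When
    ``use_content_key`` is on, reports identical on (age, sex, vaccination
    date, onset date, sorted PT set, sorted brand list) additionally collapse
    to the lowest report id.  Idempotent in both modes.
    """
    by_id: dict[str, Report] = {}
    for r in reports:
        by_id.setdefault(r.report_id, r)
    kept = list(by_id.values())

    if use_content_key:
        by_content: dict[tuple, Report] = {}
        for r in kept:
            key = (
                r.age_years,
                r.sex,
                r.vaccination_date,
                r.onset_date,
                tuple(sorted(r.pts)),
                tuple(sorted(v.brand_label for v in r.vaccines)),
            )
            prev = by_content.get(key)
            if prev is None or _id_sort_key(r.report_id) < _id_sort_key(prev.report_id):
                by_content[key] = r
        kept = sorted(by_content.values(), key=lambda r: _id_sort_key(r.report_id))

    return kept, len(reports) - len(kept)


def load_pt_soc_map(path) -> PtSocMap:
    """Load a two-column TSV (PT, SOC). Conflicting duplicate PTs are fatal."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["PT", "SOC"], "PT->SOC mapping")
    if df.empty:
        raise ValueError("PT->SOC mapping file has no rows")
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        pt, soc = row["PT"].strip(), row["SOC"].strip()
        if pt in mapping and mapping[pt] != soc:
            raise ValueError(f"conflicting SOC assignments for PT {pt!r}")
        mapping[pt] = soc
    return PtSocMap(mapping)


def load_dme_list(path) -> DmeList:
    """Load a one-column TSV (PT) of Designated Medical Events."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["PT"], "DME list")
    if df.empty:
        raise ValueError("DME list file has no rows")
    seen: dict[str, None] = {}
    for pt in df["PT"]:
        pt = pt.strip()
        if pt:
            seen.setdefault(pt)
    return DmeList(tuple(seen))


# --- normalized single-file round trip -------------------------------------

_NORM_COLUMNS = [
    "report_id", "received_date", "age_years", "sex", "vaccination_date",
    "onset_date", "outcome_flags", "vaccines", "pts",
]


def _fmt_date(d: date | None) -> str:
    return "" if d is None else d.isoformat()


def write_reports(reports: Iterable[Report], path) -> None:
    """Write normalised reports as one TSV row per report (PTs pipe-delimited)."""
    rows = []
    for r in reports:
        rows.append(
            {
                "report_id": r.report_id,
                "received_date": _fmt_date(r.received_date),
                "age_years": "" if r.age_years is None else repr(r.age_years),
                "sex": r.sex,
                "vaccination_date": _fmt_date(r.vaccination_date),
                "onset_date": _fmt_date(r.onset_date),
                "outcome_flags": "|".join(sorted(r.outcome_flags)),
                "vaccines": ";".join(
                    "~".join([v.brand_label, v.manufacturer, v.dose_series])
                    for v in r.vaccines
                ),
                "pts": "|".join(sorted(r.pts)),
            }
        )
    pd.DataFrame(rows, columns=_NORM_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_date_str(s: str) -> date | None:
    return None if not s else date.fromisoformat(s)


def read_reports(path) -> list[Report]:
    """Inverse of :func:`write_reports`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _NORM_COLUMNS, "normalized reports")
    out = []
    for _, row in df.iterrows():
        vaccines = tuple(
            VaccineEntry(*entry.split("~"))
            for entry in row["vaccines"].split(";")
            if entry
        )
        out.append(
            Report(
                report_id=row["report_id"],
                received_date=_parse_date_str(row["received_date"]),
                age_years=float(row["age_years"]) if row["age_years"] else None,
                sex=row["sex"],
                vaccination_date=_parse_date_str(row["vaccination_date"]),
                onset_date=_parse_date_str(row["onset_date"]),
                outcome_flags=frozenset(
                    f for f in row["outcome_flags"].split("|") if f
                ),
                vaccines=vaccines,
                pts=frozenset(p for p in row["pts"].split("|") if p),
            )
        )
    return out
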