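"""Synthetic VAERS-format report generator with known ground truth.

Emits the same three CSV files the ingestion layer reads — a report-level
data file, a per-vaccine file and a five-PT-slot symptoms file — for a corpus
of DTaP-exposed reports plus a non-DTaP background, with configurable
baseline PT reporting probabilities, planted (exposure, PT) relative risks,
an onset-delay model, outcome-flag probabilities, per-field missingness and
injected duplicates.  Identical config and seed give byte-identical files.

The default configuration is a deliberately stated world, loosely shaped
like the public DTaP corpus: a short-onset geometric delay (mean 2 days)
with a 1% heavy tail reaching ~15,000 days, brand/dose mixes matching the
published marginal shares, a ~1.5% fatal share, and three planted relative
risks of 3 on otherwise-null PTs.  The DTaP slice is a minority (10%) of the
corpus because in a real spontaneous-report database the exposure of
interest is a small fraction of all reports (DTaP is ~3% of VAERS), and a
dominant comparator keeps expected counts stable.  It makes no attempt to calibrate PT
marginals to the real corpus beyond orders of magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .vaers_io import DTAP_BRANDS, PtSocMap, DmeList, RawTriple

#: (PT, SOC, baseline per-report probability).  Baselines sum to ~1.1 so a
#: typical report carries one to three PTs.
PT_VOCABULARY: tuple[tuple[str, str, float], ...] = (
    ("Pyrexia", "General disorders and administration site conditions", 0.20),
    ("Injection site erythema", "General disorders and administration site conditions", 0.14),
    ("Injection site swelling", "General disorders and administration site conditions", 0.08),
    ("Injection site warmth", "General disorders and administration site conditions", 0.05),
    ("Injection site pain", "General disorders and administration site conditions", 0.04),
    ("Injection site induration", "General disorders and administration site conditions", 0.02),
    ("Feeling hot", "General disorders and administration site conditions", 0.01),
    ("Fatigue", "General disorders and administration site conditions", 0.02),
    ("Sudden infant death syndrome", "General disorders and administration site conditions", 0.004),
    ("Death", "General disorders and administration site conditions", 0.002),
    ("Erythema", "Skin and subcutaneous tissue disorders", 0.07),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.06),
    ("Urticaria", "Skin and subcutaneous tissue disorders", 0.04),
    ("Pruritus", "Skin and subcutaneous tissue disorders", 0.02),
    ("Erythema multiforme", "Skin and subcutaneous tissue disorders", 0.002),
    ("Convulsion", "Nervous system disorders", 0.02),
    ("Febrile convulsion", "Nervous system disorders", 0.01),
    ("Somnolence", "Nervous system disorders", 0.02),
    ("Hypotonia", "Nervous system disorders", 0.005),
    ("Syncope", "Nervous system disorders", 0.004),
    ("Vomiting", "Gastrointestinal disorders", 0.045),
    ("Diarrhoea", "Gastrointestinal disorders", 0.03),
    ("Nausea", "Gastrointestinal disorders", 0.01),
    ("Crying", "Psychiatric disorders", 0.05),
    ("Irritability", "Psychiatric disorders", 0.045),
    ("Agitation", "Psychiatric disorders", 0.02),
    ("Screaming", "Psychiatric disorders", 0.015),
    ("Nasopharyngitis", "Infections and infestations", 0.01),
    ("Cellulitis", "Infections and infestations", 0.006),
    ("Otitis media", "Infections and infestations", 0.005),
    ("Cough", "Respiratory, thoracic and mediastinal disorders", 0.01),
    ("Apnoea", "Respiratory, thoracic and mediastinal disorders", 0.002),
    ("Respiratory depression", "Respiratory, thoracic and mediastinal disorders", 0.0005),
    ("Hypersensitivity", "Immune system disorders", 0.008),
    ("Anaphylactic reaction", "Immune system disorders", 0.001),
    ("Angioedema", "Immune system disorders", 0.001),
    ("Cardiac arrest", "Cardiac disorders", 0.0008),
    ("Body temperature increased", "Investigations", 0.03),
    ("Blood test abnormal", "Investigations", 0.002),
    ("Lymphadenopathy", "Blood and lymphatic system disorders", 0.004),
    ("Anaemia", "Blood and lymphatic system disorders", 0.001),
    ("Aplasia pure red cell", "Blood and lymphatic system disorders", 0.0002),
    ("Pain in extremity", "Musculoskeletal and connective tissue disorders", 0.02),
    ("Myalgia", "Musculoskeletal and connective tissue disorders", 0.008),
)

#: PTs that force an outcome flag when present (SIDS is by definition fatal).
PT_FORCED_FLAGS: dict[str, str] = {
    "Sudden infant death syndrome": "DIED",
    "Death": "DIED",
    "Cardiac arrest": "DIED",
}

BRAND_MANUFACTURER = {
    "DTAP (ACEL-IMUNE)": "Pfizer\\Wyeth",
    "DTAP (CERTIVA)": "North American Vaccines",
    "DTAP (DAPTACEL)": "Sanofi Pasteur",
    "DTAP (INFANRIX)": "GlaxoSmithKline Biologicals",
    "DTAP (TRIPEDIA)": "Sanofi Pasteur",
    "DTAP (NO BRAND NAME)": "",
}

#: Fictitious non-DTaP exposures for background reports; only their
#: not-being-DTaP matters to the comparator.
BACKGROUND_BRANDS = (
    ("FLU (FICTIVAX)", "Fictive Biologics"),
    ("MMR (TOYVAX)", "Toy Vaccine Works"),
    ("HIB (DEMOVAX)", "Demo Immunologics"),
)


@dataclass
class SyntheticConfig:
    """Full generative specification; defaults are the stated world above."""

    n_dtap_reports: int = 10_000
    n_background_reports: int = 90_000
    seed: int = 42
    # Table-2-like brand mix over the six DTaP labels
    brand_mix: dict = field(default_factory=lambda: {
        "DTAP (ACEL-IMUNE)": 0.0547,
        "DTAP (CERTIVA)": 0.0012,
        "DTAP (DAPTACEL)": 0.2504,
        "DTAP (INFANRIX)": 0.3796,
        "DTAP (TRIPEDIA)": 0.2413,
        "DTAP (NO BRAND NAME)": 0.0728,
    })
    # mixture weights over the [0,2), [2,5), [5,7) age bands
    age_band_weights: tuple = (0.50, 0.30, 0.20)
    sex_probs: dict = field(default_factory=lambda: {
        "F": 0.45, "M": 0.525, "U": 0.025,
    })
    pt_vocabulary: tuple = PT_VOCABULARY
    #: (exposure brand label or "any", PT, relative risk)
    planted_signals: tuple = (
        ("DTAP (INFANRIX)", "Febrile convulsion", 3.0),
        ("any", "Injection site induration", 3.0),
        ("DTAP (DAPTACEL)", "Apnoea", 3.0),
    )
    onset_geometric_mean_days: float = 2.0
    onset_heavy_tail_prob: float = 0.01
    onset_heavy_tail_max_days: int = 15_000
    outcome_probs: dict = field(default_factory=lambda: {
        "DIED": 0.012, "L_THREAT": 0.019, "HOSPITAL": 0.10,
        "X_STAY": 0.005, "DISABLE": 0.016, "RECOVD": 0.62,
    })
    dose_probs: dict = field(default_factory=lambda: {
        "1": 0.1135, "2": 0.0917, "3": 0.0702, "4": 0.2377,
        "5": 0.3022, "6": 0.0088, "7+": 0.0006, "": 0.1753,
    })
    extra_dose_prob: float = 0.001  # chance of a second DTaP entry on a report
    missingness: dict = field(default_factory=lambda: {
        "age": 0.01, "vax_date": 0.04, "onset_date": 0.05,
    })
    duplicate_rate: float = 0.002
    first_report_id: int = 100_001

    def validate(self) -> None:
        for name, probs in (("brand_mix", self.brand_mix),
                            ("sex_probs", self.sex_probs),
                            ("dose_probs", self.dose_probs)):
            total = sum(probs.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"{name} must sum to 1 (got {total})")
        if any(rr <= 0 for _, _, rr in self.planted_signals):
            raise ValueError("relative risks must be positive")
        if not np.isclose(sum(self.age_band_weights), 1.0, atol=1e-6):
            raise ValueError("age_band_weights must sum to 1")


@dataclass
class GroundTruth:
    """Planted truth: per (exposure, PT) relative risk and injected duplicates."""

    relative_risks: dict  # (exposure, pt) -> rr, covering exactly the planted signals
    duplicates: dict      # new report id -> original report id

    def rr(self, exposure: str, pt: str) -> float:
        return self.relative_risks.get((exposure, pt), 1.0)

    @property
    def null_pts(self) -> list[str]:
        planted = {pt for _, pt in self.relative_risks}
        return [pt for pt, _, _ in PT_VOCABULARY if pt not in planted]


def toy_pt_soc_map() -> PtSocMap:
    """The generator's PT->SOC mapping, usable as the test dictionary input."""
    return PtSocMap({pt: soc for pt, soc, _ in PT_VOCABULARY})


def write_toy_pt_soc_map(path) -> None:
    pd.DataFrame(
        [(pt, soc) for pt, soc, _ in PT_VOCABULARY], columns=["PT", "SOC"]
    ).to_csv(path, sep="\t", index=False)


#: Inherently serious PTs from the vocabulary, standing in for the EMA list
#: (synthetic subset; the real 62-entry list is licensed input data).
TOY_DME_PTS = (
    "Erythema multiforme",
    "Anaphylactic reaction",
    "Angioedema",
    "Aplasia pure red cell",
    "Cardiac arrest",
    "Sudden infant death syndrome",
    "Respiratory depression",
)


def toy_dme_list() -> DmeList:
    return DmeList(TOY_DME_PTS)


def write_toy_dme_list(path) -> None:
    pd.DataFrame({"PT": TOY_DME_PTS}).to_csv(path, sep="\t", index=False)


def _fmt_dates(ordinals: np.ndarray, missing: np.ndarray) -> list[str]:
    out = []
    for o, miss in zip(ordinals, missing):
        out.append("" if miss else date.fromordinal(int(o)).strftime("%m/%d/%Y"))
    return out


def generate(
    config: SyntheticConfig | None = None, out_dir=None
) -> tuple[RawTriple, GroundTruth]:
    """Generate a synthetic corpus; optionally write the file bundle.

    Per report: demographics and brand(s) are drawn first, then each PT via an
    independent Bernoulli with probability baseline * RR(exposure, PT) capped
    at 1 (a warning lists any capped planted pair); rows left without any PT
    are redrawn; the onset date is the vaccination date plus a draw from the
    onset model; outcome flags are drawn (with PT-forced fatality); field
    missingness and duplicate injection are applied last.

    When ``out_dir`` is given, writes data.csv / vax.csv / symptoms.csv plus
    ground_truth.tsv and a config echo (config.yaml).
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_dtap, n_bg = cfg.n_dtap_reports, cfg.n_background_reports
    n = n_dtap + n_bg
    is_dtap = np.zeros(n, bool)
    is_dtap[:n_dtap] = True

    ids = np.array([str(cfg.first_report_id + i) for i in range(n)])

    # ages: band mixture over [0,2), [2,5), [5,7) for everyone (the study and
    # its comparator are both paediatric)
    bands = rng.choice(3, size=n, p=np.asarray(cfg.age_band_weights))
    lo = np.array([0.0, 2.0, 5.0])[bands]
    hi = np.array([2.0, 5.0, 7.0])[bands]
    ages = np.round(lo + (hi - lo) * rng.random(n), 2)

    sex_labels = np.array(list(cfg.sex_probs))
    sexes = sex_labels[rng.choice(len(sex_labels), size=n, p=np.array(list(cfg.sex_probs.values())))]

    # vaccination dates uniform over the study window (leaving room for the
    # receipt lag to stay inside it)
    start = date(1990, 1, 1).toordinal()
    end = date(2025, 3, 31).toordinal()
    vax_ord = rng.integers(start, end + 1, size=n)

    # brands
    brand_labels = np.array(list(cfg.brand_mix))
    dtap_brand = brand_labels[
        rng.choice(len(brand_labels), size=n, p=np.array(list(cfg.brand_mix.values())))
    ]
    bg_idx = rng.choice(len(BACKGROUND_BRANDS), size=n)

    # planted relative risks: per report x PT probability matrix
    pts = [pt for pt, _, _ in cfg.pt_vocabulary]
    baselines = np.array([b for _, _, b in cfg.pt_vocabulary])
    probs = np.tile(baselines, (n, 1))
    for exposure, pt, rr in cfg.planted_signals:
        if pt not in pts:
            raise ValueError(f"planted PT {pt!r} not in the vocabulary")
        j = pts.index(pt)
        if exposure == "any":
            exposed = is_dtap
        else:
            exposed = is_dtap & (dtap_brand == exposure)
        probs[exposed, j] *= rr
    capped = probs > 1
    if capped.any():
        bad = sorted({pts[j] for j in np.where(capped.any(axis=0))[0]})
        warnings.warn(f"probability cap hit for planted signal PT(s): {bad}", stacklevel=2)
        probs = np.minimum(probs, 1.0)

    pt_matrix = rng.random((n, len(pts))) < probs
    # every report must carry at least one PT: redraw empty rows
    for _ in range(100):
        empty = ~pt_matrix.any(axis=1)
        if not empty.any():
            break
        pt_matrix[empty] = rng.random((empty.sum(), len(pts))) < probs[empty]
    else:
        pt_matrix[~pt_matrix.any(axis=1), 0] = True  # force the most common PT

    # onset delays: geometric (support 0,1,...) with the configured mean, plus
    # a uniform heavy tail emulating multi-year late reports
    p_geom = 1.0 / (1.0 + cfg.onset_geometric_mean_days)
    delays = rng.geometric(p_geom, size=n) - 1
    tail = rng.random(n) < cfg.onset_heavy_tail_prob
    delays[tail] = rng.integers(0, cfg.onset_heavy_tail_max_days + 1, size=int(tail.sum()))
    onset_ord = vax_ord + delays
    recv_ord = onset_ord + rng.geometric(1 / 10, size=n)  # receipt lag, mean ~10d
    recv_ord = np.minimum(recv_ord, date(2025, 5, 31).toordinal())
    recv_ord = np.maximum(recv_ord, vax_ord)

    # outcome flags
    flags = {}
    for col, p in cfg.outcome_probs.items():
        flags[col] = rng.random(n) < p
    for pt, col in PT_FORCED_FLAGS.items():
        if pt in pts:
            flags[col] = flags[col] | pt_matrix[:, pts.index(pt)]
    flags["RECOVD"] = flags["RECOVD"] & ~flags["DIED"]

    # missingness
    age_missing = rng.random(n) < cfg.missingness.get("age", 0.0)
    vax_missing = rng.random(n) < cfg.missingness.get("vax_date", 0.0)
    onset_missing = rng.random(n) < cfg.missingness.get("onset_date", 0.0)

    # doses (DTaP entries only)
    dose_labels = np.array(list(cfg.dose_probs))
    doses = dose_labels[
        rng.choice(len(dose_labels), size=n, p=np.array(list(cfg.dose_probs.values())))
    ]
    extra_entry = (rng.random(n) < cfg.extra_dose_prob) & is_dtap

    # duplicates: re-emit a sample of reports under fresh ids
    n_dup = int(round(cfg.duplicate_rate * n))
    dup_src = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)
    dup_ids = np.array([str(cfg.first_report_id + n + i) for i in range(n_dup)])

    def data_frame(index: np.ndarray, id_arr: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "VAERS_ID": id_arr,
                "RECVDATE": _fmt_dates(recv_ord[index], np.zeros(len(index), bool)),
                "AGE_YRS": [
                    "" if m else f"{a:g}" for a, m in zip(ages[index], age_missing[index])
                ],
                "SEX": sexes[index],
                "DIED": np.where(flags["DIED"][index], "Y", ""),
                "L_THREAT": np.where(flags["L_THREAT"][index], "Y", ""),
                "HOSPITAL": np.where(flags["HOSPITAL"][index], "Y", ""),
                "X_STAY": np.where(flags["X_STAY"][index], "Y", ""),
                "DISABLE": np.where(flags["DISABLE"][index], "Y", ""),
                "RECOVD": np.where(flags["RECOVD"][index], "Y", ""),
                "VAX_DATE": _fmt_dates(vax_ord[index], vax_missing[index]),
                "ONSET_DATE": _fmt_dates(onset_ord[index], onset_missing[index]),
            }
        )

    all_idx = np.arange(n)
    data = pd.concat(
        [data_frame(all_idx, ids), data_frame(dup_src, dup_ids)], ignore_index=True
    )

    # vaccine rows
    vax_rows = []
    for block_idx, block_ids in ((all_idx, ids), (dup_src, dup_ids)):
        for i, rid in zip(block_idx, block_ids):
            if is_dtap[i]:
                brand = dtap_brand[i]
                vax_rows.append(
                    (rid, "DTAP", BRAND_MANUFACTURER[brand], doses[i], brand)
                )
                if extra_entry[i]:
                    vax_rows.append(
                        (rid, "DTAP", BRAND_MANUFACTURER[brand], "", brand)
                    )
            else:
                brand, manu = BACKGROUND_BRANDS[bg_idx[i]]
                vax_rows.append((rid, brand.split(" ")[0], manu, doses[i], brand))
    vax = pd.DataFrame(
        vax_rows, columns=["VAERS_ID", "VAX_TYPE", "VAX_MANU", "VAX_DOSE_SERIES", "VAX_NAME"]
    )

    # symptom rows: up to five PT slots per row
    sym_rows = []
    for block_idx, block_ids in ((all_idx, ids), (dup_src, dup_ids)):
        for i, rid in zip(block_idx, block_ids):
            report_pts = [pts[j] for j in np.flatnonzero(pt_matrix[i])]
            for s in range(0, len(report_pts), 5):
                chunk = report_pts[s : s + 5]
                chunk += [""] * (5 - len(chunk))
                sym_rows.append((rid, *chunk))
    symptoms = pd.DataFrame(
        sym_rows,
        columns=["VAERS_ID", "SYMPTOM1", "SYMPTOM2", "SYMPTOM3", "SYMPTOM4", "SYMPTOM5"],
    )

    truth = GroundTruth(
        relative_risks={(exp, pt): rr for exp, pt, rr in cfg.planted_signals},
        duplicates={d: ids[s] for d, s in zip(dup_ids, dup_src)},
    )
    triple = RawTriple(data_rows=data, vax_rows=vax, symptom_rows=symptoms)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        data.to_csv(out / "data.csv", index=False)
        vax.to_csv(out / "vax.csv", index=False)
        symptoms.to_csv(out / "symptoms.csv", index=False)
        pd.DataFrame(
            [
                {"exposure": e, "pt": p, "relative_risk": r}
                for (e, p), r in truth.relative_risks.items()
            ]
        ).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        cfg_dict = asdict(cfg)
        cfg_dict["pt_vocabulary"] = [list(t) for t in cfg_dict["pt_vocabulary"]]
        cfg_dict["planted_signals"] = [list(t) for t in cfg_dict["planted_signals"]]
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg_dict, fh, sort_keys=True)

    return triple, truth


def fixture_small() -> RawTriple:
    """Deterministic 13-row / 12-id corpus exercising every ingestion edge.

    Contains exactly one duplicate-id data-row pair, one zero-symptom report,
    one missing age, one onset-before-vaccination report, one "7+" dose and
    one PT absent from the toy mapping.  After default assembly, dedup and
    cohort filters, 10 of the 12 reports are eligible.
    """
    def drow(rid, recv, age, sex, vax_d, onset_d, **fl):
        row = {
            "VAERS_ID": rid, "RECVDATE": recv, "AGE_YRS": age, "SEX": sex,
            "DIED": "", "L_THREAT": "", "HOSPITAL": "", "X_STAY": "",
            "DISABLE": "", "RECOVD": "", "VAX_DATE": vax_d, "ONSET_DATE": onset_d,
        }
        row.update(fl)
        return row

    data = pd.DataFrame(
        [
            drow("1001", "03/10/2000", "0.5", "F", "03/01/2000", "03/02/2000", RECOVD="Y"),
            drow("1002", "05/20/2005", "1.0", "M", "05/10/2005", "05/12/2005", DIED="Y"),
            drow("1003", "07/15/2010", "2.0", "F", "07/01/2010", "07/03/2010", HOSPITAL="Y"),
            drow("1003", "07/15/2010", "2.0", "F", "07/01/2010", "07/03/2010", HOSPITAL="Y"),
            drow("1004", "05/05/2020", "6.99", "M", "05/01/2020", "05/01/2020", RECOVD="Y"),
            drow("1005", "04/01/2015", "", "F", "03/20/2015", "03/22/2015"),
            drow("1006", "06/20/2010", "3", "M", "06/10/2010", "06/05/2010"),
            drow("1007", "09/09/1999", "1.2", "U", "09/01/1999", "09/02/1999"),
            drow("1008", "10/10/2018", "4", "F", "10/01/2018", "10/02/2018",
                 HOSPITAL="Y", L_THREAT="Y"),
            drow("1009", "02/02/2002", "0.2", "M", "01/20/2002", "01/21/2002"),
            drow("1010", "11/11/2011", "5.5", "F", "11/01/2011", "11/03/2011", RECOVD="Y"),
            drow("1011", "08/08/2008", "2.5", "M", "08/01/2008", "", RECOVD="Y"),
            drow("1012", "12/12/2012", "1.8", "F", "12/01/2012", "12/04/2012", X_STAY="Y"),
        ]
    )

    def vrow(rid, brand, dose):
        return {
            "VAERS_ID": rid, "VAX_TYPE": "DTAP",
            "VAX_MANU": BRAND_MANUFACTURER.get(brand, ""),
            "VAX_DOSE_SERIES": dose, "VAX_NAME": brand,
        }

    vax = pd.DataFrame(
        [
            vrow("1001", "DTAP (INFANRIX)", "1"),
            vrow("1002", "DTAP (DAPTACEL)", "2"),
            vrow("1003", "DTAP (TRIPEDIA)", "4"),
            vrow("1004", "DTAP (INFANRIX)", "5"),
            vrow("1005", "DTAP (INFANRIX)", "3"),
            vrow("1006", "DTAP (ACEL-IMUNE)", "7+"),
            vrow("1007", "DTAP (CERTIVA)", ""),
            vrow("1008", "DTAP (NO BRAND NAME)", "4"),
            vrow("1009", "DTAP (DAPTACEL)", "1"),
            vrow("1010", "DTAP (TRIPEDIA)", "5"),
            vrow("1011", "DTAP (INFANRIX)", "3"),
            vrow("1012", "DTAP (DAPTACEL)", "1"),
        ]
    )

    def srow(rid, *pt_list):
        pts5 = list(pt_list) + [""] * (5 - len(pt_list))
        return {
            "VAERS_ID": rid, "SYMPTOM1": pts5[0], "SYMPTOM2": pts5[1],
            "SYMPTOM3": pts5[2], "SYMPTOM4": pts5[3], "SYMPTOM5": pts5[4],
        }

    symptoms = pd.DataFrame(
        [
            srow("1001", "Pyrexia", "Crying"),
            srow("1002", "Sudden infant death syndrome"),
            srow("1003", "Vomiting"),
            srow("1004", "Erythema"),
            srow("1005", "Rash"),
            srow("1006", "Urticaria"),
            srow("1007", "Zebra syndrome", "Pyrexia"),
            srow("1008", "Convulsion"),
            srow("1010", "Injection site erythema", "Pyrexia"),
            srow("1010", "Pyrexia"),
            srow("1011", "Diarrhoea"),
            srow("1012", "Pyrexia"),
        ]
    )
    return RawTriple(data_rows=data, vax_rows=vax, symptom_rows=symptoms)
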