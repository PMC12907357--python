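"""End-to-end orchestration: one config in, a reproducible output bundle out.

A run ingests (or generates) the VAERS-format triple, normalises and filters
reports, writes the descriptive tables, runs PT- and SOC-level
disproportionality overall plus the configured outcome subsets, screens
against the DME list, bins SIDS intervals, and emits plot-ready volcano and
forest data files plus a manifest recording the config hash, seed, library
versions and per-stage row accounting.  The default bundle is exactly 14
files; sex/age stratum runs add files when enabled via ``strata``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .cohort import AGE_STRATA, Cohort, CohortCriteria, derive_frame, filter_cohort
from .descriptives import (
    onset_summary,
    seriousness_summary,
    sids_interval_table,
    summarize_demographics,
    summarize_vaccines,
    yearly_series,
)
from .disprop import SignalCriteria, analyze, build_tables, volcano_table
from .screening import dme_screen, subset_signal_run
from .synthetic import SyntheticConfig, generate, toy_dme_list, toy_pt_soc_map
from .vaers_io import (
    assemble_reports,
    deduplicate,
    load_dme_list,
    load_pt_soc_map,
    read_triple,
    write_reports,
)

log = logging.getLogger("dtapsafe")


@dataclass
class RunConfig:
    """Configuration for one end-to-end run.

    Exactly one of ``synthetic`` or the real-input paths must be given.
    """

    out_dir: str = "results/run"
    synthetic: SyntheticConfig | None = None
    data_path: str | None = None
    vax_path: str | None = None
    symptoms_path: str | None = None
    pt_soc_path: str | None = None
    dme_path: str | None = None
    criteria: CohortCriteria = field(default_factory=CohortCriteria)
    signal_criteria: SignalCriteria = field(default_factory=SignalCriteria)
    content_dedup: bool = False
    subsets: tuple = ("serious", "fatal")
    strata: tuple = ()  # optional extra stratified runs: "sex" and/or "age"
    restrict_background_age: bool = True
    sids_pt_label: str = "Sudden infant death syndrome"
    q: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        real = all(p is not None for p in (self.data_path, self.vax_path, self.symptoms_path))
        if (self.synthetic is None) == (not real):
            raise ValueError("specify exactly one of synthetic config or the three input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            if isinstance(syn, dict):
                syn = {
                    k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
                    if isinstance(v, list) else v
                    for k, v in syn.items()
                }
                raw["synthetic"] = SyntheticConfig(**syn)
        for key in ("subsets", "strata"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, sep="\t", index=False)
    written.append(path)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Any stage failure aborts with the stage name and removes partial outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    t0 = time.time()
    try:
        stage = "ingest"
        if config.synthetic is not None:
            triple, _truth = generate(config.synthetic)
            pt_soc = (
                load_pt_soc_map(config.pt_soc_path)
                if config.pt_soc_path
                else toy_pt_soc_map()
            )
            dme = load_dme_list(config.dme_path) if config.dme_path else toy_dme_list()
        else:
            triple = read_triple(config.data_path, config.vax_path, config.symptoms_path)
            if config.pt_soc_path is None or config.dme_path is None:
                raise ValueError("real-data runs require pt_soc_path and dme_path")
            pt_soc = load_pt_soc_map(config.pt_soc_path)
            dme = load_dme_list(config.dme_path)
        n_raw_ids = triple.data_rows["VAERS_ID"].astype(str).str.strip().nunique()
        log.info("ingest: %d distinct report ids", n_raw_ids)

        stage = "normalize"
        reports, assemble_exclusions = assemble_reports(triple)
        reports, n_removed = deduplicate(reports, use_content_key=config.content_dedup)
        write_reports(reports, out / "normalized_reports.tsv")
        written.append(out / "normalized_reports.tsv")

        stage = "cohort"
        cohort = filter_cohort(reports, config.criteria)
        n_excluded_filter = sum(cohort.exclusions.values())
        exclusion_rows = (
            [{"stage": "assemble", "reason": k, "count": v}
             for k, v in assemble_exclusions.items()]
            + [{"stage": "dedup", "reason": "duplicate_report", "count": n_removed}]
            + [{"stage": "filter", "reason": k, "count": v}
               for k, v in cohort.exclusions.items()]
        )
        _write_tsv(pd.DataFrame(exclusion_rows), out / "exclusions.tsv", written)
        log.info("cohort: %d eligible reports", len(cohort))

        stage = "background"
        lo, hi = config.criteria.window
        background = [
            r for r in reports
            if not any(v.brand_label in config.criteria.brand_whitelist for v in r.vaccines)
            and r.received_date is not None and lo <= r.received_date <= hi
        ]
        if config.restrict_background_age:
            background = [
                r for r in background
                if r.age_years is not None
                and 0 <= r.age_years < config.criteria.max_age_years_exclusive
            ]
        if not background:
            raise ValueError("background report set is empty")

        stage = "descriptives"
        _write_tsv(
            pd.concat(
                [summarize_demographics(cohort), seriousness_summary(cohort)],
                ignore_index=True,
            ),
            out / "table1_demographics.tsv",
            written,
        )
        _write_tsv(summarize_vaccines(cohort), out / "table2_vaccines.tsv", written)
        _write_tsv(yearly_series(cohort), out / "yearly_series.tsv", written)

        stage = "signals_overall"
        pt_tables = build_tables(cohort, background, level="PT")
        pt_results = analyze(pt_tables, criteria=config.signal_criteria, q=config.q)
        _write_tsv(pt_results, out / "signals_pt_all.tsv", written)
        soc_tables = build_tables(cohort, background, level="SOC", pt_soc_map=pt_soc)
        soc_results = analyze(soc_tables, criteria=config.signal_criteria, q=config.q)
        _write_tsv(soc_results, out / "signals_soc_all.tsv", written)

        stage = "signals_subsets"
        for subset in config.subsets:
            res = subset_signal_run(
                cohort, background, subset,
                criteria=config.signal_criteria, q=config.q,
            )
            _write_tsv(res, out / f"signals_pt_{subset}.tsv", written)

        stage = "signals_strata"
        for axis in config.strata:
            if axis == "sex":
                levels = [("sex", s) for s in ("female", "male")]
            elif axis == "age":
                levels = [("age", s) for s in AGE_STRATA]
            else:
                raise ValueError(f"unknown stratum axis {axis!r}")
            for _, level_value in levels:
                if axis == "sex":
                    sub = [r for r in cohort.reports if r.sex == level_value]
                    bg = [r for r in background if r.sex == level_value]
                else:
                    def in_stratum(r):
                        from .cohort import assign_age_stratum
                        return (
                            r.age_years is not None
                            and 0 <= r.age_years < 7
                            and assign_age_stratum(r.age_years) == level_value
                        )
                    sub = [r for r in cohort.reports if in_stratum(r)]
                    bg = [r for r in background if in_stratum(r)]
                if not sub or not bg:
                    continue
                frame, n_anom = derive_frame(sub)
                sub_cohort = Cohort(reports=sub, frame=frame, n_negative_onset=n_anom)
                tables = build_tables(sub_cohort, bg, level="PT", stratum=f"{axis}:{level_value}")
                res = analyze(tables, criteria=config.signal_criteria, q=config.q)
                tag = level_value.replace(" ", "").replace("≥", "ge").replace("<", "lt")
                _write_tsv(res, out / f"signals_pt_{axis}_{tag}.tsv", written)

        stage = "dme_screen"
        dme_rows, dme_summary = dme_screen(pt_results, dme)
        summary_df = pd.DataFrame([dme_summary])
        dme_out = pd.concat(
            [summary_df, dme_rows], axis=0, ignore_index=True
        ) if len(dme_rows) else summary_df
        _write_tsv(dme_out, out / "dme_screen.tsv", written)

        stage = "sids"
        _write_tsv(
            sids_interval_table(cohort, config.sids_pt_label),
            out / "sids_intervals.tsv",
            written,
        )

        stage = "plot_data"
        _write_tsv(volcano_table(soc_results), out / "volcano_soc.tsv", written)
        forest = pt_results.sort_values("a", ascending=False).head(20)[
            ["event_label", "a", "ror", "ror_ci_low", "ror_ci_high", "positive_any"]
        ]
        _write_tsv(forest, out / "forest_pt.tsv", written)

        stage = "manifest"
        n_assembled = len(reports) + n_removed
        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed if config.synthetic is None else config.synthetic.seed,
            "versions": {
                "dtapsafe": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
            },
            "counts": {
                "raw_distinct_ids": int(n_raw_ids),
                "assembled": int(n_assembled),
                "excluded_assemble": int(assemble_exclusions["no_symptoms"]),
                "orphan_ids": int(assemble_exclusions["orphan_ids"]),
                "removed_dedup": int(n_removed),
                "cohort": len(cohort),
                "excluded_filter": int(n_excluded_filter),
                "background": len(background),
            },
            "outputs": sorted(p.name for p in written) + ["manifest.json"],
            "elapsed_seconds": round(time.time() - t0, 2),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        written.append(out / "manifest.json")
        return manifest
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
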