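"""Subset signal analyses: serious-only, fatal-only, and Designated Medical
Event (DME) screening.

Outcome-defined subsets rerun the full disproportionality pipeline on the
restricted cohort, with the comparator background restricted the same way by
default (serious DTaP vs serious non-DTaP reports), so that outcome-related
reporting propensity does not masquerade as an exposure effect.  The DME
screen cross-references already-computed PT-level results against the
EMA-style list of inherently serious events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .cohort import Cohort, classify_seriousness, derive_frame
from .disprop import GpsPrior, SignalCriteria, analyze, build_tables
from .vaers_io import DmeList, Report


def _is_serious(r: Report) -> bool:
    return classify_seriousness(r.outcome_flags)[0]


def _is_fatal(r: Report) -> bool:
    return classify_seriousness(r.outcome_flags)[1]


PREDICATES: dict[str, Callable[[Report], bool]] = {
    "all": lambda r: True,
    "serious": _is_serious,
    "fatal": _is_fatal,
}

#: Subsets whose predicate is outcome-based, triggering background matching.
OUTCOME_SUBSETS = frozenset({"serious", "fatal"})


@dataclass(frozen=True)
class SubsetSpec:
    """A named pure predicate over reports."""

    name: str

    def predicate(self) -> Callable[[Report], bool]:
        try:
            return PREDICATES[self.name]
        except KeyError:
            raise ValueError(f"unknown subset {self.name!r}") from None


def subset_signal_run(
    cohort: Cohort,
    background: Sequence[Report],
    subset: SubsetSpec | str,
    criteria: SignalCriteria | None = None,
    prior: GpsPrior | None = None,
    level: str = "PT",
    pt_soc_map=None,
    match_background: bool = True,
    q: float = 0.05,
) -> pd.DataFrame:
    """Rerun the disproportionality pipeline on a report subset.

    For outcome-based subsets the background is restricted by the same
    predicate when ``match_background`` is on.
    """
    spec = SubsetSpec(subset) if isinstance(subset, str) else subset
    pred = spec.predicate()
    sub_reports = [r for r in cohort.reports if pred(r)]
    if not sub_reports:
        raise ValueError(f"subset {spec.name!r} is empty")
    if len(sub_reports) < 10:
        warnings.warn(
            f"subset {spec.name!r} has only {len(sub_reports)} reports; "
            "disproportionality statistics will be unstable",
            stacklevel=2,
        )
    bg = list(background)
    if match_background and spec.name in OUTCOME_SUBSETS:
        bg = [r for r in bg if pred(r)]
    frame, n_anom = derive_frame(sub_reports)
    sub_cohort = Cohort(reports=sub_reports, frame=frame, n_negative_onset=n_anom)
    tables = build_tables(
        sub_cohort, bg, level=level, pt_soc_map=pt_soc_map, stratum=spec.name
    )
    return analyze(tables, criteria=criteria, prior=prior, q=q)


def dme_screen(results: pd.DataFrame, dme_list: DmeList) -> tuple[pd.DataFrame, dict]:
    """Keep PT-level results whose event label is a Designated Medical Event.

    Matching is exact string equality after trimming outer whitespace.
    Returns the kept rows and a summary with the number of matched PTs and
    how many of them are flagged positive by any method.
    """
    if len(dme_list) == 0:
        raise ValueError("DME list is empty")
    mask = results["event_label"].astype(str).str.strip().map(lambda pt: pt in dme_list)
    kept = results[mask].reset_index(drop=True)
    summary = {
        "n_dme_pts": int(len(dme_list)),
        "n_matched": int(len(kept)),
        "n_positive": int(kept["positive_any"].sum()) if len(kept) else 0,
    }
    return kept, summary
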