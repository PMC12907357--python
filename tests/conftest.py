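"""Shared fixtures: the small deterministic corpus and one large seeded
synthetic corpus reused by the recovery and acceptance tests."""

from __future__ import annotations

import warnings

import pytest

from dtapsafe.cohort import filter_cohort
from dtapsafe.synthetic import SyntheticConfig, fixture_small, generate
from dtapsafe.vaers_io import DTAP_BRANDS, assemble_reports, deduplicate


@pytest.fixture(scope="session")
def small_triple():
    return fixture_small()


@pytest.fixture(scope="session")
def small_reports(small_triple):
    reports, exclusions = assemble_reports(small_triple)
    reports, _ = deduplicate(reports)
    return reports, exclusions


@pytest.fixture(scope="session")
def small_cohort(small_reports):
    reports, _ = small_reports
    return filter_cohort(reports)


def _split_corpus(reports):
    """(cohort, paediatric non-DTaP background) from an assembled report list."""
    cohort = filter_cohort(reports)
    background = [
        r for r in reports
        if not any(v.brand_label in DTAP_BRANDS for v in r.vaccines)
        and r.age_years is not None and 0 <= r.age_years < 7
    ]
    return cohort, background


@pytest.fixture(scope="session")
def big_corpus():
    """Default stated world at full size (100k reports, seed 42).

    Returns (config, truth, cohort, background).  Session-scoped: generating
    and assembling the corpus takes ~15 s and several tests share it.
    """
    config = SyntheticConfig(seed=42)
    triple, truth = generate(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reports, _ = assemble_reports(triple)
        reports, _ = deduplicate(reports)
        cohort, background = _split_corpus(reports)
    return config, truth, cohort, background
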