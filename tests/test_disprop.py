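"""Disproportionality estimators against independent oracles, plus their
algebraic invariants."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from dtapsafe.cohort import Cohort, derive_frame
from dtapsafe.disprop import (
    CLASSIC_GPS_PRIOR,
    ContingencyTable,
    GpsPrior,
    SignalCriteria,
    analyze,
    apply_criteria,
    bcpnn_ic,
    bh_adjust,
    build_tables,
    gps_ebgm,
    gps_fit_prior,
    prr,
    ror,
    volcano_table,
)
from dtapsafe.vaers_io import Report, VaccineEntry


def _table(a, b, c, d):
    return ContingencyTable(a=a, b=b, c=c, d=d, event_label="X")


# --- independent closed-form oracles (plain-math re-implementations) --------


def _ror_oracle(a, b, c, d):
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, math.exp(math.log(est) - 1.96 * se), math.exp(math.log(est) + 1.96 * se)


def _ic_oracle(a, b, c, d):
    """Information component from the conjugate posterior means, computed
    step by step from the prior predictive probabilities."""
    n = a + b + c + d
    # posterior expectations of p(exposure), p(event) under Beta(1, 1) margins
    # with strength 2, and of the joint under the margin-scaled prior
    p_x = (a + b + 1.0) / (n + 2.0)
    p_y = (a + c + 1.0) / (n + 2.0)
    g = 1.0 / (p_x * p_y)  # joint prior strength scaled to the margins
    p_xy = (a + 1.0) / (n + g)
    return math.log2(p_xy / (p_x * p_y))


class TestRor:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((10, 10, 10, 10), (1.0, 0.2895, 3.4538)),
            ((40, 60, 20, 80), (8 / 3, 1.4166, 5.0201)),
        ],
    )
    def test_worked_tables(self, cells, expected):
        est, lo, hi = ror(_table(*cells))
        assert est == pytest.approx(expected[0], rel=1e-4)
        assert lo == pytest.approx(expected[1], rel=1e-3)
        assert hi == pytest.approx(expected[2], rel=1e-3)

    def test_matches_oracle_to_1e9(self):
        for cells in [(10, 10, 10, 10), (40, 60, 20, 80), (3, 97, 50, 950), (7, 1, 2, 400)]:
            est, lo, hi = ror(_table(*cells))
            oest, olo, ohi = _ror_oracle(*cells)
            assert est == pytest.approx(oest, abs=1e-9)
            assert lo == pytest.approx(olo, abs=1e-9)
            assert hi == pytest.approx(ohi, abs=1e-9)

    def test_haldane_zero_cell(self):
        est, lo, hi = ror(_table(5, 0, 3, 10))
        assert est == pytest.approx((5.5 * 10.5) / (0.5 * 3.5))  # 33.0
        assert lo < est < hi

    @given(
        st.integers(1, 500), st.integers(1, 500),
        st.integers(1, 500), st.integers(1, 500), st.integers(2, 5),
    )
    @settings(deadline=None, max_examples=100)
    def test_scale_invariance_of_background(self, a, b, c, d, k):
        """ROR is invariant under (c, d) -> (kc, kd); PRR and chi2 are not."""
        est1, _, _ = ror(_table(a, b, c, d))
        est2, _, _ = ror(_table(a, b, k * c, k * d))
        assert est2 == pytest.approx(est1, rel=1e-12)

    def test_chi2_not_scale_invariant_witness(self):
        """Scaling the background changes the evidence (chi2) though not the
        PRR point estimate, whose unexposed proportion c/(c+d) is unchanged."""
        p1, chi1, _ = prr(_table(40, 60, 20, 80))
        p2, chi2_, _ = prr(_table(40, 60, 40, 160))
        assert p1 == pytest.approx(p2)
        assert chi1 != pytest.approx(chi2_)


class TestPrr:
    def test_independence_table(self):
        est, chi2, p = prr(_table(10, 10, 10, 10))
        assert est == 1.0 and chi2 == 0.0 and p == 1.0

    def test_worked_table(self):
        est, chi2, _ = prr(_table(40, 60, 20, 80))
        assert est == pytest.approx(2.0)
        assert chi2 == pytest.approx(9.5238, abs=1e-4)

    def test_chi2_matches_scipy_contingency(self):
        for cells in [(40, 60, 20, 80), (13, 987, 55, 8945), (5, 5, 50, 500)]:
            a, b, c, d = cells
            _, chi2, p = prr(_table(a, b, c, d))
            expected = stats.chi2_contingency(
                [[a, b], [c, d]], correction=False
            )
            assert chi2 == pytest.approx(expected.statistic, abs=1e-9)
            assert p == pytest.approx(expected.pvalue, abs=1e-9)

    @given(
        st.integers(1, 2000), st.integers(1, 2000),
        st.integers(1, 2000), st.integers(1, 2000),
    )
    @settings(deadline=None, max_examples=200)
    def test_sign_identity_with_ror(self, a, b, c, d):
        """sign(ROR - PRR) = sign(ROR - 1) on all-positive tables."""
        r, _, _ = ror(_table(a, b, c, d))
        p, _, _ = prr(_table(a, b, c, d))
        assert math.copysign(1, r - p) == math.copysign(1, r - 1) or r == pytest.approx(p)


class TestBcpnn:
    def test_symmetric_limit_is_zero(self):
        ic, _, _ = bcpnn_ic(_table(250_000, 250_000, 250_000, 250_000))
        assert abs(ic) <= 0.01

    def test_matches_independent_oracle(self):
        for cells in [(20, 80, 100, 9800), (3, 7, 11, 400), (150, 50, 60, 900)]:
            ic, _, _ = bcpnn_ic(_table(*cells))
            assert ic == pytest.approx(_ic_oracle(*cells), abs=1e-9)

    def test_monotone_in_a_at_fixed_margins(self):
        # margins: row=100, col=110, N=10,000
        def with_a(a):
            return _table(a, 100 - a, 110 - a, 10_000 - 100 - 110 + a)

        ic5 = bcpnn_ic(with_a(5))[0]
        ic10 = bcpnn_ic(with_a(10))[0]
        assert ic10 > ic5

    def test_large_count_limit(self):
        """IC converges to log2(aN / ((a+b)(a+c))) as counts grow at fixed ratios."""
        scale = 10**6
        a, b, c, d = 2 * scale, 8 * scale, 10 * scale, 80 * scale
        ic, _, _ = bcpnn_ic(_table(a, b, c, d))
        n = a + b + c + d
        limit = math.log2(a * n / ((a + b) * (a + c)))
        assert ic == pytest.approx(limit, abs=1e-3)

    def test_ic_minus_2sd_below_ic(self):
        ic, var, low = bcpnn_ic(_table(20, 80, 100, 9800))
        assert var > 0 and low == pytest.approx(ic - 2 * math.sqrt(var))


class TestGps:
    def test_degenerate_prior_digamma_oracle(self):
        """Single Gamma(2,2) prior, a=10, E=2: posterior Gamma(12, rate 4)."""
        prior = GpsPrior(2.0, 2.0, 2.0, 2.0, 0.5)
        ebgm, ebgm05 = gps_ebgm(10, 2.0, prior)
        assert ebgm == pytest.approx(math.exp(special.digamma(12) - math.log(4)), abs=1e-6)
        assert ebgm05 == pytest.approx(stats.gamma.ppf(0.05, 12, scale=0.25), abs=1e-6)

    def test_large_count_limit(self):
        ebgm, _ = gps_ebgm(10_000, 2_000.0, CLASSIC_GPS_PRIOR)
        assert ebgm == pytest.approx(5.0, rel=0.01)

    def test_ebgm05_below_ebgm(self):
        for a, E in [(3, 0.5), (10, 2.0), (100, 30.0), (50, 200.0)]:
            ebgm, ebgm05 = gps_ebgm(a, E, CLASSIC_GPS_PRIOR)
            assert ebgm05 <= ebgm

    @given(st.integers(10, 500), st.floats(1.5, 10.0))
    @settings(deadline=None, max_examples=60)
    def test_shrinkage_direction(self, a, ratio):
        """With a unit-mean prior and a/E > 1, EBGM sits between 1 and a/E
        (checked away from the very-small-count regime where the posterior
        geometric mean can dip below 1)."""
        E = a / ratio
        ebgm, _ = gps_ebgm(a, E, CLASSIC_GPS_PRIOR)
        assert 1.0 <= ebgm <= a / E + 1e-9

    def test_fit_recovers_classic_prior(self):
        rng = np.random.default_rng(2024)
        n = 20_000
        p = CLASSIC_GPS_PRIOR
        comp = rng.random(n) < p.mix_p
        lam = np.where(
            comp,
            rng.gamma(p.alpha1, 1 / p.beta1, n),
            rng.gamma(p.alpha2, 1 / p.beta2, n),
        )
        E = np.exp(rng.uniform(np.log(0.5), np.log(500), n))
        a = rng.poisson(lam * E)
        fit = gps_fit_prior((a, E))
        for true, est in [
            (p.alpha1, fit.alpha1), (p.beta1, fit.beta1),
            (p.alpha2, fit.alpha2), (p.beta2, fit.beta2), (p.mix_p, fit.mix_p),
        ]:
            assert abs(est - true) / true <= 0.20

    def test_single_component_data_pushes_mix_to_boundary(self):
        rng = np.random.default_rng(7)
        n = 5000
        lam = rng.gamma(2.0, 1 / 4.0, n)
        E = np.exp(rng.uniform(np.log(1), np.log(100), n))
        a = rng.poisson(lam * E)
        fit = gps_fit_prior((a, E))
        # either component may absorb the data; the other's weight vanishes
        # or both components coincide at the single true gamma
        degenerate_weight = fit.mix_p <= 0.05 or fit.mix_p >= 0.95
        coincident = (
            abs(fit.alpha1 / fit.beta1 - fit.alpha2 / fit.beta2) < 0.05
        )
        assert degenerate_weight or coincident

    def test_fit_loglik_not_worse_than_start(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(2.0, 500)
        E = np.full(500, 2.0)
        fit = gps_fit_prior((a, E))
        from dtapsafe.disprop import _mixture_loglik, _prior_to_theta

        start_ll = _mixture_loglik(_prior_to_theta(CLASSIC_GPS_PRIOR), a.astype(float), E)
        assert fit.loglik >= start_ll - 1e-6

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            GpsPrior(-1, 1, 1, 1, 0.5)
        with pytest.raises(ValueError):
            GpsPrior(1, 1, 1, 1, 1.0)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.001, 0.5), (0.002, 0.5)),
            ((0.03,), (0.03,)),
        ],
    )
    def test_hand_step_up(self, p, expected):
        adjusted, _ = bh_adjust(p)
        assert adjusted == pytest.approx(expected)

    def test_monotone_and_idempotent(self):
        rng = np.random.default_rng(11)
        p = rng.random(200)
        adjusted, _ = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adjusted[order]) >= -1e-15)
        twice, _ = bh_adjust(adjusted)
        # adjusted p-values of an already-adjusted monotone vector... step-up
        # is idempotent in the rejection sense
        _, reject1 = bh_adjust(p)
        _, reject2 = bh_adjust(p)
        assert np.array_equal(reject1, reject2)
        assert np.all(adjusted >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCriteriaAndOutputs:
    def _result_row(self, **overrides):
        import pandas as pd

        base = {
            "a": 5, "ror_ci_low": 1.2, "prr": 2.5, "chi2": 9.0,
            "ic_minus_2sd": 0.5, "ebgm05": 2.5,
        }
        base.update(overrides)
        return pd.DataFrame([base])

    def test_ror_flag(self):
        out = apply_criteria(self._result_row())
        assert bool(out["sig_ror"].iloc[0])

    def test_min_a_gate_blocks_all_flags(self):
        out = apply_criteria(self._result_row(a=2))
        assert not out[["sig_ror", "sig_prr", "sig_bcpnn", "sig_mgps"]].any(axis=None)

    def test_prr_rule_is_conjunctive(self):
        out = apply_criteria(self._result_row(prr=2.5, chi2=3.9))
        assert not bool(out["sig_prr"].iloc[0])

    def test_volcano_values(self):
        import pandas as pd

        results = pd.DataFrame(
            {"event_label": ["A", "B"], "ror": [1.0, 2.0], "p_adjusted": [1.0, 0.01]}
        )
        v = volcano_table(results)
        assert v["log_ror"].iloc[0] == 0.0
        assert v["neg_log10_p_adjusted"].iloc[0] == 0.0
        assert v["neg_log10_p_adjusted"].iloc[1] == pytest.approx(2.0)


def _mk_report(i, pts, brand="DTAP (INFANRIX)"):
    return Report(
        report_id=str(i), received_date=None, age_years=1.0, sex="female",
        vaccination_date=None, onset_date=None, outcome_flags=frozenset(),
        vaccines=(VaccineEntry(brand, "", "1"),), pts=frozenset(pts),
    )


class TestBuildTables:
    def test_hand_counted_pt_table(self):
        cohort = [_mk_report(i, {"Pyrexia"} if i < 4 else {"Rash"}) for i in range(10)]
        background = [
            _mk_report(100 + i, {"Pyrexia"} if i < 10 else {"Rash"}, brand="FLU")
            for i in range(100)
        ]
        tables = {t.event_label: t for t in build_tables(cohort, background)}
        t = tables["Pyrexia"]
        assert (t.a, t.b, t.c, t.d) == (4, 6, 10, 90)

    def test_soc_level_counts_events_not_reports(self):
        from dtapsafe.vaers_io import PtSocMap

        pt_soc = PtSocMap({"Pyrexia": "General", "Fatigue": "General"})
        cohort = [_mk_report(1, {"Pyrexia", "Fatigue"})]
        background = [_mk_report(2, {"Pyrexia"}, brand="FLU")]
        tables = {t.event_label: t for t in build_tables(
            cohort, background, level="SOC", pt_soc_map=pt_soc
        )}
        assert tables["General"].a == 2  # two PTs in one SOC on one report

    def test_empty_background_fatal(self):
        with pytest.raises(ValueError):
            build_tables([_mk_report(1, {"Pyrexia"})], [])
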