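"""Disproportionality signal detection on spontaneous-report 2x2 tables.

For each exposure-event pair the standard contingency table is

    =============  =======  =========
                   event    not event
    =============  =======  =========
    exposed        a        b
    not exposed    c        d
    =============  =======  =========

over which four estimators are computed:

* ROR  — reporting odds ratio (a*d)/(b*c) with a Wald 95% CI on the log scale.
* PRR  — proportional reporting ratio [a/(a+b)]/[c/(c+d)] with the Pearson
  chi-square statistic (no continuity correction) and its 1-df p-value.
* IC   — the BCPNN information component, the posterior log2 ratio of the
  joint to the product-of-marginals report probability under the standard
  conjugate priors (Dirichlet margins with alpha1=beta1=gamma11=1,
  alpha=beta=2), with a delta-method variance and IC-2SD lower bound.
* EBGM — the empirical-Bayes geometric mean of the gamma-Poisson shrinker:
  observed counts a ~ Poisson(lambda*E) with E=(a+b)(a+c)/N, lambda drawn from
  a two-component gamma mixture prior whose five hyperparameters are fitted by
  marginal maximum likelihood; EBGM = 2^E[log2 lambda | a] and EBGM05 is the
  5th posterior percentile.

Tables with a zero cell get the Haldane–Anscombe +0.5 on all four cells
(flagged); all-positive tables are computed uncorrected.  A pair is flagged
per method by the community-standard thresholds (a>=3 plus ROR CI low > 1;
PRR>=2 & chi2>=4; IC-2SD > 0; EBGM05 > 2) and "positive any" is their OR.
The Benjamini–Hochberg step-up procedure is applied to the PRR chi-square
p-values within each analysis family (Q = 0.05 by default).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import Cohort
from .vaers_io import PtSocMap, Report


@dataclass(frozen=True)
class ContingencyTable:
    """One exposure-event 2x2 table in one stratum."""

    a: int
    b: int
    c: int
    d: int
    exposure_label: str = "DTaP"
    event_label: str = ""
    level: str = "PT"  # "PT" or "SOC"
    stratum: str = "all"

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count E = (a+b)(a+c)/N under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.N


@dataclass(frozen=True)
class GpsPrior:
    """Two-component gamma mixture prior on the Poisson rate multiplier.

    Component k has shape ``alpha_k`` and rate ``beta_k`` (mean alpha/beta);
    ``mix_p`` is the weight of component 1.  ``loglik`` records the marginal
    log-likelihood at the fitted values when produced by :func:`gps_fit_prior`.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mix_p: float
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not (0 < self.mix_p < 1):
            raise ValueError("mix_p must lie strictly in (0, 1)")


#: The classic gamma-Poisson shrinker starting prior.
CLASSIC_GPS_PRIOR = GpsPrior(0.2, 0.1, 2.0, 4.0, 1 / 3)


@dataclass(frozen=True)
class SignalCriteria:
    """Per-method signal thresholds; a pair is positive if any method fires."""

    min_a: int = 3
    ror_ci_low_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic_low_gt: float = 0.0
    ebgm05_gt: float = 2.0


def haldane_cells(table: ContingencyTable) -> tuple[float, float, float, float, bool]:
    """Cells with the Haldane–Anscombe +0.5 applied only when any cell is 0."""
    cells = (table.a, table.b, table.c, table.d)
    if min(cells) == 0:
        return tuple(x + 0.5 for x in cells) + (True,)  # type: ignore[return-value]
    return cells + (False,)  # type: ignore[return-value]


def ror(table: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI (zero cells Haldane-corrected)."""
    a, b, c, d, _ = haldane_cells(table)
    estimate = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_r = np.log(estimate)
    return (
        float(estimate),
        float(np.exp(log_r - 1.96 * se)),
        float(np.exp(log_r + 1.96 * se)),
    )


def prr(table: ContingencyTable) -> tuple[float, float, float]:
    """PRR with the identity-form Pearson chi-square (no Yates correction)."""
    a, b, c, d, _ = haldane_cells(table)
    n = a + b + c + d
    estimate = (a / (a + b)) / (c / (c + d))
    chi2 = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return float(estimate), float(chi2), p_value


# BCPNN conjugate hyperparameters (standard 1998 convention)
_BC_ALPHA1 = _BC_BETA1 = _BC_GAMMA11 = 1.0
_BC_ALPHA = _BC_BETA = 2.0


def bcpnn_ic(table: ContingencyTable) -> tuple[float, float, float]:
    """Closed-form BCPNN information component, variance, and IC-2SD."""
    a, N = float(table.a), float(table.N)
    row = a + table.b  # exposed margin
    col = a + table.c  # event margin
    gamma = (
        _BC_GAMMA11 * (N + _BC_ALPHA) * (N + _BC_BETA)
        / ((row + _BC_ALPHA1) * (col + _BC_BETA1))
    )
    ic = np.log2(
        (a + _BC_GAMMA11) * (N + _BC_ALPHA) * (N + _BC_BETA)
        / ((N + gamma) * (row + _BC_ALPHA1) * (col + _BC_BETA1))
    )
    variance = (1 / np.log(2)) ** 2 * (
        (N - a + gamma - _BC_GAMMA11) / ((a + _BC_GAMMA11) * (1 + N + gamma))
        + (N - row + _BC_ALPHA - _BC_ALPHA1) / ((row + _BC_ALPHA1) * (1 + N + _BC_ALPHA))
        + (N - col + _BC_BETA - _BC_BETA1) / ((col + _BC_BETA1) * (1 + N + _BC_BETA))
    )
    return float(ic), float(variance), float(ic - 2 * np.sqrt(variance))


# --- gamma-Poisson shrinker -------------------------------------------------


def _log_nb(a: np.ndarray, alpha: float, beta: float, E: np.ndarray) -> np.ndarray:
    """Log marginal P(a | E) for lambda ~ Gamma(alpha, rate beta): a negative
    binomial with size alpha and success probability beta/(beta+E)."""
    return (
        special.gammaln(a + alpha)
        - special.gammaln(alpha)
        - special.gammaln(a + 1)
        + alpha * (np.log(beta) - np.log(beta + E))
        + a * (np.log(E) - np.log(beta + E))
    )


def _mixture_loglik(theta: np.ndarray, a: np.ndarray, E: np.ndarray) -> float:
    la1, lb1, la2, lb2, logit_p = theta
    alpha1, beta1 = np.exp(la1), np.exp(lb1)
    alpha2, beta2 = np.exp(la2), np.exp(lb2)
    p = special.expit(logit_p)
    l1 = np.log(p) + _log_nb(a, alpha1, beta1, E)
    l2 = np.log1p(-p) + _log_nb(a, alpha2, beta2, E)
    return float(np.sum(np.logaddexp(l1, l2)))


def _prior_to_theta(prior: GpsPrior) -> np.ndarray:
    return np.array(
        [
            np.log(prior.alpha1), np.log(prior.beta1),
            np.log(prior.alpha2), np.log(prior.beta2),
            special.logit(prior.mix_p),
        ]
    )


_DEFAULT_STARTS = (
    CLASSIC_GPS_PRIOR,
    GpsPrior(1.0, 1.0, 1.0, 2.0, 0.5),
    GpsPrior(0.5, 0.5, 3.0, 3.0, 0.2),
)


def gps_fit_prior(
    tables: Sequence[ContingencyTable] | tuple[np.ndarray, np.ndarray],
    starts: Sequence[GpsPrior] = _DEFAULT_STARTS,
    tol: float = 1e-8,
) -> GpsPrior:
    """Fit the five mixture-prior hyperparameters by marginal maximum likelihood.

    ``tables`` is either a list of contingency tables (``a`` and ``E`` taken
    per table) or an ``(a, E)`` array pair.  The negative marginal
    log-likelihood of the induced two-component negative-binomial mixture is
    minimised with L-BFGS-B over log/logit-transformed parameters, from at
    least three starting points including the classic (0.2, 0.1, 2, 4, 1/3).
    The returned prior is canonicalised so component 1 has the larger mean.
    """
    if isinstance(tables, tuple):
        a, E = np.asarray(tables[0], float), np.asarray(tables[1], float)
    else:
        a = np.array([t.a for t in tables], float)
        E = np.array([t.expected for t in tables], float)
    if np.any(E <= 0):
        raise ValueError("all expected counts must be positive")

    best: optimize.OptimizeResult | None = None
    start_ll = max(_mixture_loglik(_prior_to_theta(s), a, E) for s in starts)
    for s in starts:
        theta0 = _prior_to_theta(s)
        res = optimize.minimize(
            lambda th: -_mixture_loglik(th, a, E),
            theta0,
            method="L-BFGS-B",
            options={"ftol": tol, "maxiter": 2000},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            "gamma-Poisson prior fit failed to converge from every start; "
            f"n_cells={len(a)}, starts={len(starts)}"
        )
    la1, lb1, la2, lb2, logit_p = best.x
    fitted = GpsPrior(
        float(np.exp(la1)), float(np.exp(lb1)),
        float(np.exp(la2)), float(np.exp(lb2)),
        float(special.expit(logit_p)),
        loglik=float(-best.fun),
    )
    if fitted.loglik < start_ll - 1e-6:
        raise RuntimeError("optimizer returned a worse likelihood than its start")
    # canonical order: component with the larger prior mean first
    if fitted.alpha1 / fitted.beta1 < fitted.alpha2 / fitted.beta2:
        fitted = replace(
            fitted,
            alpha1=fitted.alpha2, beta1=fitted.beta2,
            alpha2=fitted.alpha1, beta2=fitted.beta1,
            mix_p=1 - fitted.mix_p,
        )
    return fitted


def _posterior_weights(a: float, E: float, prior: GpsPrior) -> tuple[float, float]:
    arr = np.array([a], float)
    earr = np.array([E], float)
    l1 = np.log(prior.mix_p) + _log_nb(arr, prior.alpha1, prior.beta1, earr)[0]
    l2 = np.log1p(-prior.mix_p) + _log_nb(arr, prior.alpha2, prior.beta2, earr)[0]
    m = max(l1, l2)
    w1 = np.exp(l1 - m)
    w2 = np.exp(l2 - m)
    q1 = w1 / (w1 + w2)
    return float(q1), float(1 - q1)


def gps_ebgm(a: int, E: float, prior: GpsPrior) -> tuple[float, float]:
    """Posterior EBGM and its 5th percentile (EBGM05) for one cell.

    The posterior on the rate multiplier is the two-gamma mixture with
    components Gamma(alpha_k + a, rate beta_k + E) and weights proportional to
    each component's marginal likelihood.  EBGM is the posterior geometric
    mean exp(E[ln lambda]) computed via the digamma function; EBGM05 solves
    the mixture CDF = 0.05 by bracketed root finding.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    q1, q2 = _posterior_weights(a, E, prior)
    shapes = (prior.alpha1 + a, prior.alpha2 + a)
    rates = (prior.beta1 + E, prior.beta2 + E)
    mean_log = q1 * (special.digamma(shapes[0]) - np.log(rates[0])) + q2 * (
        special.digamma(shapes[1]) - np.log(rates[1])
    )
    ebgm = float(np.exp(mean_log))

    def cdf(x: float) -> float:
        return q1 * stats.gamma.cdf(x, shapes[0], scale=1 / rates[0]) + q2 * stats.gamma.cdf(
            x, shapes[1], scale=1 / rates[1]
        )

    hi = a / E * 10 + 10
    while cdf(hi) < 0.05:  # defensive; the bracket is generous already
        hi *= 10
    ebgm05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, 1e-8, hi, xtol=1e-9))
    return ebgm, ebgm05


def bh_adjust(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: adjusted p-values and rejection flags.

    adjusted_(i) = min over j >= rank(i) of m*p_(j)/j, capped at 1; reject
    when adjusted <= q.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted, adjusted <= q


# --- table construction -----------------------------------------------------


def _pt_counts(reports: Sequence[Report]) -> Counter:
    counts: Counter = Counter()
    for r in reports:
        counts.update(r.pts)  # pts is a set: one count per report
    return counts


def _soc_event_counts(reports: Sequence[Report], pt_soc_map: PtSocMap) -> tuple[Counter, int]:
    """Event-level SOC counts: every PT occurrence maps to its SOC, so one
    report with two PTs in a SOC contributes 2.  Returns (counts, total)."""
    counts: Counter = Counter()
    total = 0
    for r in reports:
        for pt in r.pts:
            counts[pt_soc_map.get(pt)] += 1
            total += 1
    return counts, total


def build_tables(
    cohort: Cohort | Sequence[Report],
    background: Sequence[Report],
    level: str = "PT",
    pt_soc_map: PtSocMap | None = None,
    exposure_label: str = "DTaP",
    stratum: str = "all",
) -> list[ContingencyTable]:
    """One contingency table per event label with at least one exposed count.

    At PT level, ``a`` counts exposed reports containing the PT (repetition
    within a report does not multiply).  At SOC level counts are event-level:
    each PT occurrence contributes to its SOC, so SOC totals may exceed report
    counts.  ``background`` is the unexposed comparator report set.
    """
    exposed = cohort.reports if isinstance(cohort, Cohort) else list(cohort)
    background = list(background)
    if not background:
        raise ValueError("background report set is empty")

    if level == "PT":
        exp_counts = _pt_counts(exposed)
        bg_counts = _pt_counts(background)
        n_exp, n_bg = len(exposed), len(background)
    elif level == "SOC":
        if pt_soc_map is None:
            raise ValueError("SOC-level tables require a PT->SOC mapping")
        exp_counts, n_exp = _soc_event_counts(exposed, pt_soc_map)
        bg_counts, n_bg = _soc_event_counts(background, pt_soc_map)
    else:
        raise ValueError(f"unknown level {level!r}")

    tables = []
    for event in sorted(exp_counts):
        a = exp_counts[event]
        c = bg_counts.get(event, 0)
        tables.append(
            ContingencyTable(
                a=a, b=n_exp - a, c=c, d=n_bg - c,
                exposure_label=exposure_label, event_label=event,
                level=level, stratum=stratum,
            )
        )
    return tables


# --- full analysis ----------------------------------------------------------

RESULT_COLUMNS = [
    "event_label", "level", "stratum", "a", "b", "c", "d", "expected",
    "ror", "ror_ci_low", "ror_ci_high", "prr", "chi2", "p_value", "p_adjusted",
    "ic", "ic_variance", "ic_minus_2sd", "ebgm", "ebgm05",
    "sig_ror", "sig_prr", "sig_bcpnn", "sig_mgps", "positive_any",
    "bh_reject", "zero_cell_corrected",
]


def apply_criteria(results: pd.DataFrame, criteria: SignalCriteria | None = None) -> pd.DataFrame:
    """Set the per-method flags and the any-of positivity on a result frame."""
    criteria = criteria or SignalCriteria()
    out = results.copy()
    enough = out["a"] >= criteria.min_a
    out["sig_ror"] = enough & (out["ror_ci_low"] > criteria.ror_ci_low_gt)
    out["sig_prr"] = enough & (out["prr"] >= criteria.prr_min) & (out["chi2"] >= criteria.chi2_min)
    out["sig_bcpnn"] = enough & (out["ic_minus_2sd"] > criteria.ic_low_gt)
    out["sig_mgps"] = enough & (out["ebgm05"] > criteria.ebgm05_gt)
    out["positive_any"] = out["sig_ror"] | out["sig_prr"] | out["sig_bcpnn"] | out["sig_mgps"]
    return out


def analyze(
    tables: Sequence[ContingencyTable],
    criteria: SignalCriteria | None = None,
    prior: GpsPrior | None = None,
    q: float = 0.05,
    min_tables_for_fit: int = 50,
) -> pd.DataFrame:
    """Compute all four statistics, BH adjustment, and flags for one family.

    The gamma-mixture prior is fitted across the supplied tables when there
    are at least ``min_tables_for_fit`` of them and no prior is given;
    otherwise the classic prior is used (with a warning), since a handful of
    cells cannot identify five hyperparameters.  BH adjustment treats the
    supplied tables as one multiplicity family.
    """
    if not tables:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    if prior is None:
        if len(tables) >= min_tables_for_fit:
            prior = gps_fit_prior(tables)
        else:
            warnings.warn(
                f"only {len(tables)} tables: using the classic gamma-mixture "
                "prior instead of fitting",
                stacklevel=2,
            )
            prior = CLASSIC_GPS_PRIOR

    rows = []
    for t in tables:
        ror_v, ror_lo, ror_hi = ror(t)
        prr_v, chi2_v, p_v = prr(t)
        ic_v, ic_var, ic_lo = bcpnn_ic(t)
        ebgm_v, ebgm05_v = gps_ebgm(t.a, t.expected, prior)
        corrected = min(t.a, t.b, t.c, t.d) == 0
        rows.append(
            {
                "event_label": t.event_label, "level": t.level, "stratum": t.stratum,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d, "expected": t.expected,
                "ror": ror_v, "ror_ci_low": ror_lo, "ror_ci_high": ror_hi,
                "prr": prr_v, "chi2": chi2_v, "p_value": p_v,
                "ic": ic_v, "ic_variance": ic_var, "ic_minus_2sd": ic_lo,
                "ebgm": ebgm_v, "ebgm05": ebgm05_v,
                "zero_cell_corrected": corrected,
            }
        )
    df = pd.DataFrame(rows)
    adjusted, reject = bh_adjust(df["p_value"].to_numpy(), q=q)
    df["p_adjusted"] = adjusted
    df["bh_reject"] = reject
    df = apply_criteria(df, criteria)
    return df[RESULT_COLUMNS]


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot data: natural-log ROR vs -log10 adjusted p."""
    return pd.DataFrame(
        {
            "event_label": results["event_label"],
            "log_ror": np.log(results["ror"]),
            "neg_log10_p_adjusted": -np.log10(results["p_adjusted"]),
        }
    )
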