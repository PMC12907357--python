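# Methods

## Study design

The pipeline mirrors a standard spontaneous-report ("case/non-case")
pharmacovigilance study. The exposure cohort is every deduplicated report of
a child under 7 years carrying at least one of the six DTaP brand labels
(`DTAP (ACEL-IMUNE)`, `(CERTIVA)`, `(DAPTACEL)`, `(INFANRIX)`, `(TRIPEDIA)`,
`(NO BRAND NAME)`), received between 1990-01-01 and 2025-05-31. The
comparator ("background") is every other report in the loaded corpus; by
default it is restricted to the same age range as the cohort, so that age
structure does not masquerade as an exposure effect in subgroup runs. The
window filter applies to the *received* date; the vaccination date may
precede the window.

Because young children routinely receive several vaccines at one visit,
DTaP exposure is one of possibly many per report; nothing in the design
attributes causality, and concomitant exposures are a known confounder of
every spontaneous-report analysis.

## Ingestion and deduplication

The VAERS public layout is a CSV triple: a report-level data file, a
per-vaccine file, and a symptoms file whose rows carry up to five MedDRA
Preferred Terms (PTs); reports with more than five coded events span
multiple rows, and PTs are unioned per report. Unparseable dates become
missing — rows are never dropped for formatting. Reports with no PT at all
are excluded and counted; ids present only in the vaccine/symptom files
never form reports.

Deduplication is by report id (first occurrence wins). A secondary
content-tuple collapse — identical (age, sex, vaccination date, onset date,
sorted PTs, sorted brands) keeping the lowest id — exists but is **off by
default**: the upstream database's own dedup key is not public, duplication
is reportedly very limited, and an aggressive content key risks collapsing
genuinely distinct same-day siblings. Both modes are idempotent and the
accounting identity (raw distinct ids = kept + excluded + removed) is
enforced in tests and in the run manifest.

PT strings are compared after trimming outer whitespace, case-sensitively
(MedDRA PTs are canonically cased). The PT→SOC mapping is user-supplied data
because MedDRA is licensed; unknown PTs fall into an explicit `UNMAPPED`
bucket rather than being dropped.

## Derived variables

- **Age strata**: half-open bins [0,2), [2,5), [5,7), forced by the label
  set `<2`, `≥2 and <5`, `≥5 and <7`. Reported age is used as given;
  reports with missing age are excluded from the cohort (no imputation).
- **Onset days**: onset date minus vaccination date in calendar days;
  either date missing → missing; a negative difference → missing plus a
  logged anomaly (a valid report cannot have onset before vaccination, and
  the plausible minimum is 0).
- **Seriousness**: the regulatory definition — any of death,
  life-threatening event, hospitalization, prolonged hospitalization,
  disability. Fatal ⇔ the death flag.
- **Primary outcome**: the published tables present mutually exclusive
  outcome counts without stating a rule, so a severity-ordered precedence is
  used: Died > Life threatening > Prolonged hospitalization > Hospitalized >
  Disability > Recovered; no flags → N/A. The precedence is a parameter.

Percentages in frequency tables are 100·count/denominator rounded half-up to
two decimals, matching the printed style; nonzero counts that round to 0.00
display as `<0.01%`. Report-level tables use the report count as the
denominator; the vaccine table uses the count of administered whitelisted
doses, which can exceed the report count — the two denominators are carried
explicitly and never mixed.

## Disproportionality estimators

All four operate on the 2×2 table (a,b,c,d) with N = a+b+c+d and expected
count E = (a+b)(a+c)/N. Exact forms (the pinned conventions):

- **ROR** = ad/bc; 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
- **PRR** = [a/(a+b)]/[c/(c+d)]; χ² is the identity-form Pearson statistic
  (ad−bc)²·N/[(a+b)(c+d)(a+c)(b+d)] without Yates correction, with the 1-df
  upper-tail p-value.
- **BCPNN IC** (closed form, 1998 convention): with γ₁₁ = α₁ = β₁ = 1 and
  α = β = 2, γ = γ₁₁(N+α)(N+β)/[(a+b+α₁)(a+c+β₁)],
  IC = log₂[(a+γ₁₁)(N+α)(N+β)/((N+γ)(a+b+α₁)(a+c+β₁))], with the matching
  delta-method variance and IC−2SD = IC − 2·√V.
- **Gamma-Poisson shrinker**: prior λ ~ p·Gamma(α₁,β₁) + (1−p)·Gamma(α₂,β₂)
  (rate parametrization). The marginal of a is a two-component negative
  binomial mixture; the five hyperparameters are fitted by maximizing the
  summed log marginal likelihood with L-BFGS-B over log/logit-transformed
  parameters from ≥3 starts including the classic (0.2, 0.1, 2, 4, 1/3),
  ftol 1e-8; non-convergence from every start is fatal. The fitted prior is
  canonicalised so component 1 has the larger mean (the mixture likelihood
  is label-symmetric). The posterior is the two-gamma mixture
  Gamma(αₖ+a, βₖ+E) with weights from the component marginal likelihoods;
  EBGM = exp(ΣQₖ(ψ(αₖ+a) − ln(βₖ+E))) via the digamma function, and EBGM05
  solves the mixture CDF = 0.05 by Brent root finding on the bracket
  [1e-8, 10·a/E + 10] (xtol 1e-9).

**Zero cells**: the Haldane–Anscombe +0.5 is added to all four cells only
when some cell is zero, and the result is flagged; nonzero tables are
bit-identical to the uncorrected formulas.

**Prior fitting threshold**: the five-parameter mixture is fitted only when
an analysis family has ≥ 50 tables; smaller families fall back to the
classic prior with a warning, since a handful of cells cannot identify five
hyperparameters. The default synthetic vocabulary has 44 PTs, so toy-scale
runs use the classic prior; real VAERS corpora (thousands of PTs) fit.

**Signal rule**: per-method thresholds (ROR CI low > 1; PRR ≥ 2 ∧ χ² ≥ 4;
IC−2SD > 0; EBGM05 > 2), each gated by a ≥ 3; positivity is the OR of the
four ("any-of"). All thresholds are configurable. BH adjustment of the PRR
χ² p-values is applied within each analysis family (the overall PT set; each
subset separately) at Q = 0.05.

**Table levels**: PT tables count reports (a PT repeated within a report
counts once). SOC tables are event-level — each PT occurrence maps to its
SOC — so SOC totals may exceed report counts; this matches the convention in
which a SOC's `a` aggregates all constituent PT occurrences.

## Subset and DME screening

Serious-only and fatal-only runs restrict the cohort by the outcome
predicate and, by default, restrict the background the same way (serious
DTaP vs serious non-DTaP): without outcome matching, differential
seriousness of reporting would dominate the contrast. The switch is
exposed. The DME screen is an exact-match (after trim) cross-reference of
PT-level results against a user-supplied Designated Medical Event list; the
shipped seven-entry list is a synthetic stand-in built from the generator's
vocabulary — the real EMA list (62 PTs) is input data.

The SIDS analysis restricts to fatal reports whose PT set contains the SIDS
label and bins the vaccination-to-onset interval into 0–6, 7–13, 14–20,
21–28, ≥29 days and NA, with per-bin counts, shares of all SIDS cases, and
mean in-bin intervals.

## The synthetic world

The generator emits the exact three-file layout the ingester reads, plus a
ground-truth file. Stated defaults, chosen once:

- **Composition**: 10,000 DTaP reports and 90,000 background reports. In a
  real spontaneous-report database the exposure of interest is a small
  slice of the corpus (DTaP is roughly 3% of all VAERS reports), and a
  dominant comparator keeps expected counts stable; 10% is a compromise
  between realism and runtime.
- **Demographics**: ages from the band mixture 50/30/20% over [0,2)/[2,5)/
  [5,7) (matching the published age split); sex 45% female / 52.5% male /
  2.5% unknown.
- **Brands and doses**: brand mix and dose-in-series distribution follow the
  published dose-level marginals, including the literal `7+` token and a
  ~17.5% missing dose share; manufacturers are derived from brand.
  Background reports carry fictitious non-DTaP labels — only their
  not-being-DTaP matters.
- **Events**: a 44-PT vocabulary over 12 SOCs with baseline per-report
  probabilities summing to ~1.1 (one to three PTs per typical report); each
  PT is an independent Bernoulli with probability baseline × RR(exposure),
  capped at 1 with a warning; empty reports are redrawn. Three planted
  signals, all RR = 3: Febrile convulsion on Infanrix, Injection site
  induration on any DTaP, Apnoea on Daptacel (the last with expected
  exposed count ≈ 15, deliberately below the a ≥ 30 recovery gate).
- **Onset**: geometric delay with mean 2 days plus a 1% uniform heavy tail
  up to 15,000 days, emulating the multi-year maximum onsets seen in real
  data so moment/median robustness is exercised.
- **Outcomes**: baseline flag probabilities giving ~13–15% serious and
  ~1.5–2% fatal shares; SIDS, Death and Cardiac arrest PTs force the death
  flag.
- **Noise**: 1% missing age, 4%/5% missing vaccination/onset dates, 0.2%
  duplicate reports re-emitted under fresh ids (recorded in the ground
  truth).

What the generator does **not** emulate: correlated PT co-occurrence,
reporting-propensity drift over calendar time, brand–era confounding,
free-text narratives, and real-corpus PT marginals beyond orders of
magnitude. A green recovery test therefore establishes that the estimators
and plumbing work on a corpus of realistic shape — not that the published
full-corpus values (158 positive signals, the specific per-PT statistics,
median onset exactly 1.0 day) are reproduced; those require the real
multi-million-report corpus.

## Numerical notes

- Percent rounding uses decimal half-up (not banker's rounding) to two
  places.
- `bh_adjust` is the exact step-up: adjusted₍ᵢ₎ = min over j ≥ rank(i) of
  m·p₍ⱼ₎/j, capped at 1. It is monotone in the raw p-values and a pure
  function of them; note that re-applying the procedure to its own adjusted
  values changes them (the step-up transform is not idempotent on its
  output), so "rerun stability" means determinism, which is what is tested.
- EBGM shrinkage direction (1 ≤ EBGM ≤ a/E when a/E > 1 under the unit-mean
  classic prior) holds away from the very-small-count regime; at a ≲ 5 the
  posterior geometric mean can legitimately fall below 1. The property is
  tested over a ∈ [10, 500].
- The onset-interval anomaly policy (negative → missing + logged) means
  onset summaries are computed over non-negative intervals only.
- Determinism: every random draw flows from one `numpy` Generator seeded by
  the config; identical config + seed gives byte-identical output files.

## Known limitations

- No multi-item (interaction) gamma-Poisson shrinker, no stratified
  Mantel–Haenszel pooling, no temporal scan statistics.
- No causality assessment: flags are reporting-disproportionality signals,
  not risks; the package deliberately computes nothing that implies
  attribution.
- The editorial treatment of borderline adjusted p-values (0.05–0.12) in
  published analyses is not reproduced; the pipeline reports flags and
  adjusted p-values and leaves interpretation to the analyst.
- With the content-dedup heuristic off (default), injected same-content
  duplicates under fresh ids remain in the corpus, as they would in a real
  passive-surveillance download.
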