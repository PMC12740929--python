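# Methods

## Case/non-case disproportionality

The analysis is a case/non-case comparison on a deduplicated store of
spontaneous reports. The *target* cohort is every case naming the drug of
interest as Primary Suspect (PS); everything else — including cases where
the target appears only as secondary suspect, concomitant or interacting
drug — is background. The counting unit is the distinct (case, Preferred
Term) pair: a case reporting k distinct PTs contributes k pairs, and a PT
mentioned twice in one case counts once. For a term t,

- a = target pairs with t, b = target pairs with other terms,
- c = background pairs with t, d = background pairs with other terms,

so the margins a+b and c+d are constant across terms at one level. System
Organ Class tables sum member-PT a and c (cumulative occurrences — a case
under several PTs of one SOC is counted once per PT, not once per SOC) and
recompute b, d from the unchanged margins.

Four estimators are computed per table, in their closed-form versions, all
sharing the log-scale standard error SE = √(1/a + 1/b + 1/c + 1/d):

| statistic | formula | lower bound |
|---|---|---|
| ROR | ad/bc | exp(ln ROR − 1.96·SE) |
| PRR, χ² | [a/(a+b)]/[c/(c+d)]; (ad−bc)²N/[(a+b)(c+d)(a+c)(b+d)] | — |
| IC | log₂[aN/((a+c)(a+b))] | IC025 = IC − 1.96·SE/ln 2 |
| EBGM | aN/((a+c)(a+b)) | EBGM05 = exp(ln EBGM − 1.96·SE) |

Conventions worth stating explicitly:

- **IC025 is an "IC − 2SD" bound.** A multiplicative CI of the form
  exp(ln IC ± z·SE) is undefined whenever IC ≤ 0, yet negative IC025
  values are meaningful and routinely reported; the subtractive form (in
  log₂ units) is the convention that reproduces published lower bounds and
  stays defined everywhere. The same reconstruction applied to the
  reference cohort's Death row (ROR CI 3.70–4.44 ⇒ SE ≈ 0.0465) returns
  its published EBGM05 (3.55) and IC025 (≈1.83 vs the printed 1.82;
  the residual is rounding of the printed inputs).
- **EBGM05 uses 1.96 SE despite the "05" name.** This matches published
  values; a strict one-sided 5th percentile (1.645·SE) is available via
  `mgps_ebgm(..., strict_5th=True)`.
- **EBGM here is the unshrunk observed/expected ratio**, so IC ≡
  log₂(EBGM) holds identically (and is property-tested). Full gamma-Poisson
  shrinkage (true MGPS) and Bayesian BCPNN posteriors are out of scope;
  for the large-margin tables this pipeline targets the difference is
  small, but for very small counts the unshrunk estimates are
  anti-conservative relative to shrunk ones.
- **Zero cells** receive the Haldane–Anscombe +0.5 on all four cells
  before any estimate (flagged in the output). Since signals require
  n ≥ 3, a is positive for any flagged term; the correction matters for
  rare background terms (c = 0).
- **Signal definition** is the conjunction n ≥ 3, ROR lower CI > 1,
  PRR ≥ 2 with χ² ≥ 4, IC025 > 0, EBGM05 > 2; every violated clause is
  recorded. All thresholds are configurable (`SignalCriteria`). Rankings:
  "frequency" = descending n, "strength" = descending EBGM05, ties broken
  alphabetically. No multiple-testing correction is applied — these
  criteria are screening thresholds, not hypothesis tests.

## Ingestion and deduplication

FAERS distributes quarterly `$`-delimited ASCII tables; a comma-separated
dialect with identical column names is supported for readable fixtures.
Rows with the wrong field count are counted and skipped, never fatal; a
missing file or unknown dialect is fatal. Dates parse at day (8-digit),
month (6-digit) or year (4-digit) precision; anything else is absent.
Deduplication keeps, per case identifier, the version with the latest FDA
receipt date, breaking ties by the highest report version and then by
input order (deterministic); absent dates sort lowest. Completeness
filtering removes cases lacking any drug or any reaction row. Incomplete
*event dates* do not remove a case — they only exclude it from the
time-to-onset analysis, which is the less destructive of the two possible
readings and the one used by default throughout.

Drug names are lower-cased, trimmed, punctuation-collapsed and mapped
through a synonym table (shipping with roflumilast/Daliresp/Daxas,
user-extensible via a two-column CSV).

## Time-to-onset and the Weibull model

TTO = EVENT_DT − START_DT in days, computed only where both dates are
day-precise; negative intervals (onset before treatment start) are
excluded and counted, as are each other exclusion reason, so records plus
exclusions always account for the full target cohort. With several
therapy rows for the target drug, the earliest complete start date is the
onset origin (earliest exposure is the conservative choice).

Quantiles use the inverse-ECDF convention (R type 1), under which each
quartile is an observed value — the convention consistent with onset IQRs
that include 0 — and the method is a parameter for anyone preferring
interpolation. Bins are half-open: [0,30), [30,180), [180,360),
[360,720), [720,∞).

The Weibull fit maximises the two-parameter likelihood (scipy MLE with
location fixed at 0). Same-day events stay in the descriptive summaries
but enter the likelihood as 0.5 days: the support is strictly positive,
and 0.5 is the midpoint of the [0,1) interval that a same-calendar-day
onset actually represents. Wald 95% CIs come from the finite-difference
observed information on (log β, log α), exponentiated back; a percentile
bootstrap is available (`ci_method="bootstrap"`). Fits require n ≥ 10 and
non-degenerate data. The hazard-pattern call uses the CI, not the point
estimate: early-failure when the β CI lies wholly below 1, wear-out
wholly above, random otherwise. The reference cohort's published fit
(β = 0.573, CI 0.539–0.607; α = 38.653 d) is an early-failure pattern;
note that one published table transposes the α and β column headings —
the scale is the ~38.7-day quantity, the shape the ~0.57 one, which is
the only physically coherent reading given the 4-day median.

## Descriptive summaries

Each categorical summary reports counts and percentages with the sum of
emitted bin counts as denominator, including an explicit unknown bin.
Age and weight bins are left-closed on their printed labels ("65–75" =
[65, 75), ">75" = [75, ∞)) — the only convention under which the
conventional labels partition the axis. Outcomes are counted per mention:
a case may carry several outcome codes and a case with none contributes
one "unknown" mention, which is the convention under which published
outcome tables sum to more mentions than cases (3,639 vs 3,140 in the
reference cohort). The serious-outcome fraction is the share of mentions
that are death, life-threatening, hospitalization or disability. Published
reference tables use the sum of their own emitted rows as denominator
(3,139 for the gender rows), not the stated cohort total; this package is
internally consistent the same way.

## Synthetic cohorts

The generator emulates the structural features the pipeline must survive:
multiple report versions per case (duplicates perturb only the DEMO
row — FDA date and version — so dedup correctness is exactly checkable),
PS/SS/C/I roles with the target emitted under verbatim synonym variants, a
small fraction of background cases carrying the target in a concomitant
role (which a correct PS filter must ignore), partially missing dates and
demographics, and one-to-many reactions.

Reactions per case: k ~ Poisson(λ = 2.5) truncated to k ≥ 1; k PTs are
drawn with replacement from a weighted vocabulary and collapsed to
distinct terms. This makes each PT's per-case inclusion probability exactly
computable from the truncated-Poisson generating function, and the ground
truth stores these expectations so recovery tests can use exact binomial
bounds rather than approximations. Injected associations multiply a PT's
draw share by its relative risk while only non-injected PTs renormalise,
so the injected share rises by exactly the configured RR.

Onset dates are back-computed as therapy start + ⌊w⌋ days with
w ~ Weibull(β = 0.573, α = 38.653 d): calendar-date differences floor
fractional onsets, and flooring is the convention consistent with the
0.5-day zero replacement above. Defaults mirror the reference cohort:
3,140 target cases; per-date missingness 0.48 so that (1−0.48)² ≈ 27% of
target cases carry a computable TTO (837/3,140 in the reference);
demographic, reporter, country and outcome marginals set to the reference
cohort's frequencies. The background is 20,000 cases — the package's
working scale for a background universe; real FAERS backgrounds are three
orders of magnitude larger, which narrows CIs and is why published
absolute χ²/IC025 values for a real cohort are far larger than synthetic
ones at this scale. What passing recovery tests shows is that the pipeline
flags what was injected and nothing else *under this generative model*;
the generator deliberately omits real-data features such as correlated
drug co-reporting, reporting-rate secular trends, term-preference biases
and duplicated cases with discrepant content.

Determinism: every draw flows from the single config seed; a fixed config
is byte-identical on disk, which the tests hash.

## Problem sizes

The shipped verification runs use 1,000 random tables for estimator
equivalence, the full default synthetic cohort (3,140 + 20,000 cases) for
end-to-end signal recovery, and 200 replicates at n = 1,000 for Weibull
shape recovery (mean β̂ within 2%, CI coverage within [90%, 99%]); the
complete run takes a few seconds on one CPU.

## Known limitations

- Unshrunk EBGM/IC (see above): no empirical-Bayes stabilisation of rare
  cells.
- Duplicate detection is by case identifier and version only; no
  probabilistic record linkage across distinct identifiers.
- MedDRA content is user-supplied: the PT→SOC map is an input (two-column
  CSV), and PTs missing from it are a hard error at SOC aggregation, never
  silently dropped. HLT/HLGT levels and SMQs are not modelled.
- The Weibull model assumes complete (uncensored) onset intervals;
  interval-censoring from date truncation and competing risks are ignored.
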