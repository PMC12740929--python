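# faersig

Disproportionality signal detection and time-to-onset modelling for
FAERS-style spontaneous adverse-event reports.

## The problem

Spontaneous-report databases such as the FDA Adverse Event Reporting System
(FAERS) collect adverse-event (AE) reports for marketed drugs. Because
there is no denominator of exposed patients, drug safety signals are found
by *disproportionality*: comparing how often a drug–event pair is reported
against the background of all other drugs, via a 2×2 table per MedDRA
Preferred Term (PT),

|                | target AE | all other AEs |
|----------------|-----------|---------------|
| target drug    | a         | b             |
| all other drugs| c         | d             |

where the counting unit is the (case, PT) pair. `faersig` implements the
full pipeline used in such pharmacovigilance studies — here built around a
roflumilast (PDE4-inhibitor) cohort as the reference worked example:

* **Ingestion** of FAERS quarterly `$`-delimited ASCII tables (DEMO, DRUG,
  REAC, THER) or an equivalent CSV dialect; case deduplication (latest FDA
  receipt date, then highest report version); verbatim drug-name
  normalisation through a synonym table (`DALIRESP`/`Daxas` →
  `roflumilast`); selection of reports naming the target as Primary
  Suspect (PS).
* **Four disproportionality statistics** with joint signal criteria:
  * ROR = ad/bc, 95% CI = exp(ln ROR ± 1.96·SE), SE = √(1/a+1/b+1/c+1/d)
  * PRR = [a/(a+b)]/[c/(c+d)], χ² = (ad−bc)²N/[(a+b)(c+d)(a+c)(b+d)]
  * IC = log₂[aN/((a+c)(a+b))], IC025 = IC − 1.96·SE/ln 2
  * EBGM = aN/((a+c)(a+b)) (unshrunk), EBGM05 = exp(ln EBGM − 1.96·SE)

  A PT is a signal when jointly n ≥ 3, ROR lower CI > 1, PRR ≥ 2 with
  χ² ≥ 4, IC025 > 0 and EBGM05 > 2. PT tables aggregate to System Organ
  Class (SOC) level by summing a and c over member PTs.
* **Time-to-onset (TTO)**: days from therapy start (START_DT) to event
  onset (EVENT_DT); median/IQR, conventional bins, and a maximum-likelihood
  Weibull fit whose shape β classifies the hazard pattern (β < 1
  early-failure, β ≈ 1 random, β > 1 wear-out, judged by the 95% CI of β).
* **Descriptives**: demographics, reporter, country, per-mention outcome
  counts, indications, yearly report counts.
* **Synthetic cohorts**: a seeded generator emulating FAERS structure
  (report versions, drug roles, missing dates, Weibull onsets, injected
  drug–AE associations of known relative risk) with a ground-truth answer
  key, so the whole pipeline is testable without any FAERS download.

## Worked example

```python
from faersig import (DisproportionalityAnalysis, WeibullOnsetModel,
                     apply_completeness_filter, compute_tto, deduplicate,
                     read_quarter, select_primary_suspect)
from faersig.synth import SynthConfig, generate

ds = generate(SynthConfig(seed=1))          # 3,140 target + 20,000 background cases
paths = ds.write("scratch/demo")
store = apply_completeness_filter(deduplicate(read_quarter(
    paths["DEMO"], paths["DRUG"], paths["REAC"], paths["THER"], "simple-csv")))

res = DisproportionalityAnalysis(store, "roflumilast", pt_soc_map=ds.pt_soc_map).fit()
print(res.summary())

targets = select_primary_suspect(store, "roflumilast")
records, _ = compute_tto(store, targets, target_canonical_name="roflumilast")
fit = WeibullOnsetModel.from_records(records).fit()
print(fit.summary().T)
```

prints (abridged):

```
Disproportionality analysis
===========================
target drug:        roflumilast
target cases (PS):  3140
background cases:   20000
PTs evaluated:      28
PT signals:         6

top signals by frequency:
                                 term   n   ROR  ROR_low  ROR_high   PRR    chi2  IC025  EBGM05
                            diarrhoea 714  5.25     4.74      5.80  4.87 1270.22   1.52    2.87
                             insomnia 626  6.72     5.99      7.52  6.27 1415.66   1.70    3.24
chronic obstructive pulmonary disease 357 24.06    19.20     30.16 23.04 1620.68   2.19    4.56
                   decreased appetite 318  6.30     5.39      7.36  6.09  693.15   1.61    3.06
                     weight decreased 297  7.47     6.31      8.85  7.23  747.30   1.72    3.29
                    suicidal ideation 199  7.53     6.13      9.26  7.37  506.45   1.68    3.19
                               0
n                            814
shape_beta               0.57632
shape_low               0.546475
shape_high              0.607796
scale_alpha_days       39.969252
classification     early-failure
```

All six injected associations (relative risks 5–25) are flagged and none
of the 22 null PTs are; the Weibull shape estimate (β̂ = 0.576, CI
0.546–0.608) recovers the generating early-failure pattern (β = 0.573). The same stages are available from the
shell:

```sh
faersig simulate --seed 1 --out-dir scratch/raw
faersig ingest   --in-dir scratch/raw --out-dir scratch/store
faersig report   --in-dir scratch/store --drug roflumilast \
                 --pt-soc-map scratch/raw/pt_soc_map.csv --out-dir scratch/out
```

## Layout

```
src/faersig/
  store.py          ingestion, deduplication, PS selection (ReportStore)
  contingency.py    (case, PT) pair counting, PT→SOC aggregation
  stats.py          ROR / PRR-χ² / IC / EBGM, signal criteria, ranking
  model.py          DisproportionalityAnalysis / DisproportionalityResults
  tto.py            TTO records, bins, quantiles, WeibullOnsetModel
  descriptives.py   categorical summaries, outcomes, yearly counts
  synth.py          seeded FAERS-like generator + GroundTruth
  datasets.py       published reference-cohort aggregates (worked examples)
  cli.py            faersig simulate/ingest/signals/tto/describe/report
docs/methods.md     model assumptions, conventions and limitations
```
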