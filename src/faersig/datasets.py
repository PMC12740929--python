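"""Reference aggregates from a published FAERS roflumilast cohort.

Worked-example inputs: summary counts reported for the roflumilast
primary-suspect cohort extracted from FAERS (2004 through 2025Q1; 3,140
deduplicated reports, 837 with a computable time-to-onset).  They let the
descriptive and time-to-onset operations be exercised against published
numbers without any FAERS download.  Only aggregates are stored — the
underlying reports are not redistributable at case level.
"""

from __future__ import annotations

__all__ = [
    "SEX_COUNTS",
    "OUTCOME_MENTION_COUNTS",
    "ONSET_BIN_COUNTS",
    "ONSET_BIN_REPRESENTATIVE_DAYS",
    "SOC_PAIR_COUNTS",
    "SIGNAL_PT_COUNTS_BY_SOC",
    "DEATH_ROW",
    "WEIBULL_FIT_REFERENCE",
]

#: gender distribution of the cohort's reports
SEX_COUNTS = {"male": 1442, "female": 1276, "unknown": 421}

#: outcome mentions (a report can carry several outcome codes; reports with
#: none count as one 'unknown' mention)
OUTCOME_MENTION_COUNTS = {
    "other": 816,
    "hospitalization": 741,
    "life-threatening": 93,
    "disability": 37,
    "death": 625,
    "unknown": 1119,
    "congenital anomaly": 1,
    "required-intervention": 207,
}

#: time-to-onset counts over the conventional bins (n = 837)
ONSET_BIN_COUNTS = {"<30": 603, "30-180": 169, "180-360": 46, "360-720": 11, ">720": 8}

#: a representative day value inside each bin, for reconstructing a record
#: set with the published bin counts
ONSET_BIN_REPRESENTATIVE_DAYS = {"<30": 4, "30-180": 100, "180-360": 200, "360-720": 400, ">720": 800}

#: cumulative (case, PT) pair counts per System Organ Class among the
#: cohort's positive-signal PTs
SOC_PAIR_COUNTS = {
    "Gastrointestinal disorders": 808,
    "Psychiatric disorders": 781,
    "General disorders and administration site conditions": 586,
    "Nervous system disorders": 565,
    "Respiratory, thoracic and mediastinal disorders": 530,
    "Investigations": 401,
    "Metabolism and nutrition disorders": 230,
    "Musculoskeletal and connective tissue disorders": 126,
    "Injury, poisoning and procedural complications": 72,
    "Cardiac disorders": 15,
    "Social circumstances": 8,
    "Infections and infestations": 3,
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)": 3,
}

#: number of distinct positive-signal PT categories per SOC (30 signal PTs
#: fan out to 52 SOC assignments in the published ranking)
SIGNAL_PT_COUNTS_BY_SOC = {
    "Psychiatric disorders": 13,
    "Respiratory, thoracic and mediastinal disorders": 8,
    "Investigations": 6,
    "General disorders and administration site conditions": 5,
    "Gastrointestinal disorders": 4,
    "Nervous system disorders": 4,
    "Cardiac disorders": 3,
    "Metabolism and nutrition disorders": 3,
    "Injury, poisoning and procedural complications": 2,
    "Infections and infestations": 1,
    "Musculoskeletal and connective tissue disorders": 1,
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)": 1,
    "Social circumstances": 1,
}

#: the cohort's most frequent signal (the 'Death' PT row): published ROR
#: with its 95% CI, the PRR (which equals the unshrunk EBGM at background
#: scale), and the published lower bounds — used to validate the EBGM05 and
#: IC025 conventions by reconstruction from the CI width
DEATH_ROW = {
    "n": 497,
    "ror": 4.06,
    "ror_low": 3.70,
    "ror_high": 4.44,
    "prr": 3.89,
    "ic025": 1.82,
    "ebgm05": 3.55,
}

#: published Weibull time-to-onset fit for the cohort (early-failure)
WEIBULL_FIT_REFERENCE = {
    "n": 837,
    "shape_beta": 0.573,
    "shape_ci": (0.539, 0.607),
    "scale_alpha_days": 38.653,
    "scale_ci": (32.893, 44.413),
    "median_days": 4,
    "iqr_days": (0, 34),
}
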