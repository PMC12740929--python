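"""Descriptive summaries of a report cohort: demographics, reporters,
countries, outcomes, indications and yearly report counts.

Categorical percentages use the sum of the emitted bin counts as the
denominator (each summary is internally consistent even when some fields
are unknown for part of the cohort).  Outcomes are counted per mention —
one case can carry several outcome codes, and a case with none contributes
a single 'unknown' mention — which is the convention under which published
outcome tables sum to more mentions than cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .store import ReportStore

__all__ = [
    "CategoricalSummary",
    "summarize_categorical",
    "serious_outcome_fraction",
    "yearly_counts",
    "AGE_BINS",
    "WEIGHT_BINS",
    "SERIOUS_OUTCOMES",
]

#: left-closed age bins [low, high) and labels
AGE_BINS = [(0, 18, "<18"), (18, 45, "18-44"), (45, 65, "45-64"), (65, 75, "65-75"), (75, np.inf, ">75")]
#: left-closed weight bins in kg
WEIGHT_BINS = [(0, 50, "<50 kg"), (50, 100, "50 kg-100 kg"), (100, np.inf, ">100 kg")]

SERIOUS_OUTCOMES = frozenset({"death", "life-threatening", "hospitalization", "disability"})

_FIELDS = ("sex", "age", "weight", "reporter", "country", "outcome", "indication", "year")


@dataclass
class CategoricalSummary:
    field: str
    rows: pd.DataFrame  # columns: label, count, percent
    denominator: int

    @classmethod
    def from_counts(cls, field: str, counts: dict[str, int]) -> "CategoricalSummary":
        """Build a summary directly from label -> count pairs; percentages
        are 100*count/sum(counts) rounded to 2 decimals."""
        denom = int(sum(counts.values()))
        rows = pd.DataFrame(
            [(label, int(c), round(100.0 * c / denom, 2) if denom else 0.0) for label, c in counts.items()],
            columns=["label", "count", "percent"],
        )
        return cls(field=field, rows=rows, denominator=denom)

    def percent_of(self, label: str) -> float:
        match = self.rows.loc[self.rows["label"] == label, "percent"]
        if match.empty:
            raise KeyError(f"label {label!r} not in summary {self.field!r}")
        return float(match.iloc[0])

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _bin_numeric(values: pd.Series, bins) -> dict[str, int]:
    counts = {label: 0 for _, _, label in bins}
    counts["unknown"] = int(values.isna().sum())
    v = values.dropna()
    for low, high, label in bins:
        counts[label] = int(((v >= low) & (v < high)).sum())
    return counts


def summarize_categorical(store: ReportStore, field: str, binning=None) -> CategoricalSummary:
    """Counts and percentages for one report characteristic.

    ``field`` is one of sex, age, weight, reporter, country, outcome,
    indication or year.  ``binning`` overrides the default age/weight bin
    edges (list of (low, high, label) with left-closed intervals).
    Indications are taken from the indication PT of primary-suspect drug
    rows (first non-empty per case).
    """
    demo = store.demo
    if field == "sex":
        counts = demo["sex"].value_counts().to_dict()
    elif field == "age":
        counts = _bin_numeric(demo["age_years"], binning or AGE_BINS)
    elif field == "weight":
        counts = _bin_numeric(demo["weight_kg"], binning or WEIGHT_BINS)
    elif field == "reporter":
        counts = demo["reporter"].value_counts().to_dict()
    elif field == "country":
        counts = demo["country"].fillna("unknown").value_counts().to_dict()
    elif field == "outcome":
        mentions: list[str] = []
        for out in demo["outcomes"].fillna(""):
            labels = [o for o in str(out).split(",") if o]
            mentions.extend(labels if labels else ["unknown"])
        counts = pd.Series(mentions).value_counts().to_dict() if mentions else {}
    elif field == "indication":
        ps = store.drugs.loc[(store.drugs["role"] == "PS") & (store.drugs["indication_pt"] != "")]
        first = ps.groupby("case_id")["indication_pt"].first()
        counts = first.value_counts().to_dict()
    elif field == "year":
        counts = {str(y): int(c) for y, c in demo["report_year"].value_counts().sort_index().items()}
    else:
        raise ValueError(f"unknown field {field!r}; expected one of {_FIELDS}")
    # stable ordering: descending count, then label
    ordered = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return CategoricalSummary.from_counts(field, ordered)


def serious_outcome_fraction(store: ReportStore) -> float:
    """Percentage of outcome mentions that are serious (death,
    life-threatening, hospitalization or disability), over all outcome
    mentions including 'unknown'."""
    if len(store.demo) == 0:
        raise ValueError("serious_outcome_fraction: empty store")
    summary = summarize_categorical(store, "outcome")
    counts = dict(zip(summary.rows["label"], summary.rows["count"]))
    serious = sum(c for label, c in counts.items() if label in SERIOUS_OUTCOMES)
    return 100.0 * serious / summary.denominator


def yearly_counts(store: ReportStore) -> pd.DataFrame:
    """Reports per calendar year, with gap years filled as 0."""
    years = store.demo.loc[store.demo["report_year"] > 0, "report_year"]
    if years.empty:
        return pd.DataFrame(columns=["year", "count"])
    counts = years.value_counts().sort_index()
    full = range(int(counts.index.min()), int(counts.index.max()) + 1)
    counts = counts.reindex(full, fill_value=0)
    return pd.DataFrame({"year": counts.index, "count": counts.to_numpy()})
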