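"""2x2 contingency tables per MedDRA term for case/non-case analysis.

The counting unit is the (case, Preferred Term) pair: a case reporting k
distinct PTs contributes k pairs, duplicate mentions of one PT within a case
count once.  For a term t and a target drug,

    a = target-drug pairs with t        b = target-drug pairs with other terms
    c = other-drug pairs with t         d = other-drug pairs with other terms

so the margins a+b (total target pairs) and c+d (total background pairs) are
the same for every term at a given level.  System Organ Class (SOC) tables
are formed by summing member-PT a and c (cumulative occurrences — a case may
appear under several PTs of one SOC) and recomputing b, d from the fixed
margins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .store import ReportStore

__all__ = ["ContingencyTable", "PtSocMap", "build_pt_tables", "aggregate_soc", "tables_to_frame"]


@dataclass(frozen=True)
class ContingencyTable:
    term: str
    level: str  # "PT" or "SOC"
    a: float
    b: float
    c: float
    d: float

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in table for {self.term!r}")


class PtSocMap:
    """Total mapping from Preferred Term to its primary System Organ Class.

    Lookup is case-insensitive on the PT.  Unmapped PTs are reported by
    :meth:`unmapped`, never silently dropped.
    """

    def __init__(self, mapping: dict[str, str]):
        self._map = {pt.strip().lower(): soc.strip() for pt, soc in mapping.items()}

    @classmethod
    def from_csv(cls, path: str | Path) -> "PtSocMap":
        df = pd.read_csv(path, dtype=str).fillna("")
        if df.shape[1] < 2:
            raise ValueError(f"PT->SOC map {path} needs two columns (pt, soc)")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def __getitem__(self, pt: str) -> str:
        return self._map[pt.strip().lower()]

    def __contains__(self, pt: str) -> bool:
        return pt.strip().lower() in self._map

    def __len__(self) -> int:
        return len(self._map)

    def unmapped(self, pts) -> list[str]:
        return sorted({pt for pt in pts if pt not in self})


def _case_pt_pairs(store: ReportStore) -> pd.DataFrame:
    """Distinct (case_id, pt_name) pairs over the whole store."""
    return store.reactions[["case_id", "pt_name"]].drop_duplicates()


def build_pt_tables(store: ReportStore, target_case_ids: set[str]) -> list[ContingencyTable]:
    """One table per PT observed anywhere in the store.

    Cases not in ``target_case_ids`` form the background ("all other
    drugs"), including cases where the target drug appears in a
    non-primary-suspect role.
    """
    if not target_case_ids:
        raise ValueError("no target reports: the target case-id set is empty")
    pairs = _case_pt_pairs(store)
    is_target = pairs["case_id"].isin(target_case_ids)
    total_target = int(is_target.sum())
    total_background = int((~is_target).sum())
    a_counts = pairs.loc[is_target, "pt_name"].value_counts()
    c_counts = pairs.loc[~is_target, "pt_name"].value_counts()
    tables = []
    for pt in sorted(set(a_counts.index) | set(c_counts.index)):
        a = int(a_counts.get(pt, 0))
        c = int(c_counts.get(pt, 0))
        tables.append(ContingencyTable(pt, "PT", a, total_target - a, c, total_background - c))
    return tables


def aggregate_soc(pt_tables: list[ContingencyTable], pt_soc_map: PtSocMap) -> list[ContingencyTable]:
    """Aggregate PT tables to SOC level by summing a and c per SOC.

    b and d are recomputed from the (unchanged) level margins, so the SOC
    margins equal the PT margins.  Every PT must be mapped.
    """
    missing = pt_soc_map.unmapped(t.term for t in pt_tables)
    if missing:
        raise KeyError(f"PTs missing from the PT->SOC map: {missing}")
    if not pt_tables:
        return []
    total_target = pt_tables[0].a + pt_tables[0].b
    total_background = pt_tables[0].c + pt_tables[0].d
    sums: dict[str, list[float]] = {}
    for t in pt_tables:
        soc = pt_soc_map[t.term]
        acc = sums.setdefault(soc, [0, 0])
        acc[0] += t.a
        acc[1] += t.c
    return [
        ContingencyTable(soc, "SOC", a, total_target - a, c, total_background - c)
        for soc, (a, c) in sorted(sums.items())
    ]


def tables_to_frame(tables: list[ContingencyTable]) -> pd.DataFrame:
    """Export as a DataFrame with columns term, level, a, b, c, d."""
    return pd.DataFrame(
        [(t.term, t.level, t.a, t.b, t.c, t.d) for t in tables],
        columns=["term", "level", "a", "b", "c", "d"],
    )
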