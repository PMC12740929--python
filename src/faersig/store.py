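"""Spontaneous-report store: ingestion, deduplication and cohort selection.

The FDA Adverse Event Reporting System (FAERS) distributes quarterly
"$"-delimited ASCII tables: DEMO (one row per report version, demographics),
DRUG (one row per reported drug, with a role code), REAC (one row per MedDRA
Preferred Term) and THER (therapy dates per drug row).  A case may appear
several times as successive report versions; analysis keeps only the latest
version of each case, then restricts to cases naming the drug of interest as
Primary Suspect (PS).

This module reads either the FAERS ASCII dialect or an equivalent
comma-separated dialect with the same column names, normalises fields into
pandas DataFrames, and implements the deduplication, drug-name normalisation,
primary-suspect selection and completeness filters of a standard FAERS
pipeline.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReportStore",
    "read_quarter",
    "deduplicate",
    "normalize_drug_name",
    "select_primary_suspect",
    "apply_completeness_filter",
    "DEFAULT_SYNONYMS",
    "load_synonym_table",
]

DIALECTS = ("faers-ascii", "simple-csv")

DEMO_COLUMNS = [
    "caseid", "caseversion", "fda_dt", "event_dt", "sex", "age", "age_cod",
    "wt", "wt_cod", "occp_cod", "occr_country", "outc_cod",
]
DRUG_COLUMNS = ["caseid", "drug_seq", "role_cod", "drugname", "indi_pt"]
REAC_COLUMNS = ["caseid", "pt"]
THER_COLUMNS = ["caseid", "dsg_drug_seq", "start_dt"]

#: occupation (reporter) codes -> reporter type
_OCCP_MAP = {
    "CN": "consumer", "MD": "physician", "PH": "pharmacist",
    "HP": "other", "LW": "other", "OT": "other",
}

#: outcome codes -> outcome labels
OUTCOME_CODES = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital anomaly",
    "RI": "required-intervention",
    "OT": "other",
}

#: age-unit codes -> multiplier to years
_AGE_UNIT_YEARS = {
    "YR": 1.0, "": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25, "DY": 1.0 / 365.25, "HR": 1.0 / (24 * 365.25),
}

#: default verbatim -> ingredient synonym table (user-extensible)
DEFAULT_SYNONYMS = {
    "daliresp": "roflumilast",
    "daxas": "roflumilast",
    "roflumilast": "roflumilast",
}

_PUNCT_RE = re.compile(r"[^\w\s]+")
_WS_RE = re.compile(r"\s+")


def normalize_drug_name(verbatim: str, synonyms: dict[str, str] | None = None) -> str:
    """Normalise a verbatim drug name and map it through a synonym table.

    Lower-cases, trims, collapses punctuation runs to single spaces, then
    looks the result up in ``synonyms`` (default: the built-in roflumilast
    table).  Unmapped names pass through in normalised form.
    """
    if synonyms is None:
        synonyms = DEFAULT_SYNONYMS
    name = _PUNCT_RE.sub(" ", str(verbatim).lower())
    name = _WS_RE.sub(" ", name).strip()
    return synonyms.get(name, name)


def load_synonym_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (verbatim, canonical) CSV into a synonym dict.

    Keys are normalised the same way verbatim names are, so lookups are
    insensitive to case/punctuation.  The built-in defaults stay active
    underneath user entries.
    """
    table = dict(DEFAULT_SYNONYMS)
    df = pd.read_csv(path, dtype=str).fillna("")
    if df.shape[1] < 2:
        raise ValueError(f"synonym table {path} needs two columns (verbatim, canonical)")
    for verbatim, canonical in zip(df.iloc[:, 0], df.iloc[:, 1]):
        key = _WS_RE.sub(" ", _PUNCT_RE.sub(" ", verbatim.lower())).strip()
        table[key] = canonical.strip().lower()
    return table


def _parse_date(raw: str) -> tuple[pd.Timestamp, str]:
    """Parse a FAERS date string; returns (timestamp, precision).

    8-digit YYYYMMDD parses fully ('day'); 6-digit YYYYMM and 4-digit YYYY
    are retained at reduced precision (anchored to the first day of the
    period); anything else is absent (NaT, precision '').
    """
    raw = str(raw).strip()
    if not raw.isdigit():
        return pd.NaT, ""
    try:
        if len(raw) == 8:
            return pd.Timestamp(f"{raw[:4]}-{raw[4:6]}-{raw[6:]}"), "day"
        if len(raw) == 6:
            return pd.Timestamp(f"{raw[:4]}-{raw[4:]}-01"), "month"
        if len(raw) == 4:
            return pd.Timestamp(f"{raw}-01-01"), "year"
    except ValueError:
        pass
    return pd.NaT, ""


@dataclass
class ReportStore:
    """Columnar store of case reports, drug entries and reactions.

    Attributes
    ----------
    demo : DataFrame
        One row per (case_id, report_version) before deduplication, one per
        case_id after.  Columns: case_id, report_version, fda_dt (raw),
        fda_date, event_dt (raw), event_date, event_precision, sex,
        age_years, weight_kg, reporter, country, outcomes (comma-joined
        labels), report_year.
    drugs : DataFrame
        case_id, drug_seq, role, verbatim_name, canonical_name,
        indication_pt, start_dt (raw), start_date, start_precision.
    reactions : DataFrame
        case_id, pt_name.
    provenance : list of str
        Human-readable log of counts in/out of every ingestion/filter step.
    """

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    @property
    def case_ids(self) -> set[str]:
        return set(self.demo["case_id"])

    def __len__(self) -> int:
        return len(self.demo)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def check_integrity(self) -> None:
        """Raise if a drug or reaction row references an unknown case."""
        cases = self.case_ids
        for name, frame in (("drugs", self.drugs), ("reactions", self.reactions)):
            orphans = set(frame["case_id"]) - cases
            if orphans:
                raise ValueError(f"{name} rows reference unknown case_ids: {sorted(orphans)[:5]}")

    def subset(self, case_ids: set[str]) -> "ReportStore":
        """Restrict all three tables to the given cases (provenance inherited)."""
        keep = self.demo["case_id"].isin(case_ids)
        return ReportStore(
            demo=self.demo.loc[keep].reset_index(drop=True),
            drugs=self.drugs.loc[self.drugs["case_id"].isin(case_ids)].reset_index(drop=True),
            reactions=self.reactions.loc[self.reactions["case_id"].isin(case_ids)].reset_index(drop=True),
            provenance=list(self.provenance),
        )

    def write_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.demo.to_csv(out / "demo.csv", index=False)
        self.drugs.to_csv(out / "drugs.csv", index=False)
        self.reactions.to_csv(out / "reactions.csv", index=False)
        (out / "provenance.txt").write_text("\n".join(self.provenance) + "\n")

    @classmethod
    def read_csv(cls, in_dir: str | Path) -> "ReportStore":
        src = Path(in_dir)
        demo = pd.read_csv(src / "demo.csv", dtype={"case_id": str, "fda_dt": str, "event_dt": str})
        for col in ("fda_date", "event_date"):
            demo[col] = pd.to_datetime(demo[col], errors="coerce")
        demo["outcomes"] = demo["outcomes"].fillna("")
        demo["event_precision"] = demo["event_precision"].fillna("")
        drugs = pd.read_csv(src / "drugs.csv", dtype={"case_id": str, "start_dt": str})
        drugs["start_date"] = pd.to_datetime(drugs["start_date"], errors="coerce")
        drugs["start_precision"] = drugs["start_precision"].fillna("")
        drugs["indication_pt"] = drugs["indication_pt"].fillna("")
        reactions = pd.read_csv(src / "reactions.csv", dtype={"case_id": str})
        prov_path = src / "provenance.txt"
        prov = prov_path.read_text().splitlines() if prov_path.exists() else []
        return cls(demo=demo, drugs=drugs, reactions=reactions, provenance=prov)


def _read_table(path: Path, dialect: str, expected_cols: list[str]) -> tuple[list[list[str]], int]:
    """Read one delimited table; returns (rows, n_malformed).

    Rows whose field count differs from the header's are counted as
    malformed and dropped, never fatal.  The FAERS ASCII dialect is a plain
    "$" split (FAERS files carry no quoting); the simple-csv dialect goes
    through the csv module.
    """
    text = path.read_text(encoding="utf-8", errors="replace")
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        return [], 0
    if dialect == "faers-ascii":
        raw_rows = [ln.split("$") for ln in lines]
    else:
        raw_rows = list(csv.reader(lines))
    header = [h.strip().lower() for h in raw_rows[0]]
    missing = [c for c in expected_cols if c not in header]
    if missing:
        raise ValueError(f"{path} is missing required columns: {missing}")
    idx = [header.index(c) for c in expected_cols]
    rows, malformed = [], 0
    for raw in raw_rows[1:]:
        if len(raw) != len(header):
            malformed += 1
            continue
        rows.append([raw[i].strip() for i in idx])
    return rows, malformed


def read_quarter(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    ther_path: str | Path | None = None,
    dialect: str = "simple-csv",
    synonyms: dict[str, str] | None = None,
) -> ReportStore:
    """Load one quarterly file set into a :class:`ReportStore`.

    Therapy start dates from THER are joined onto drug rows by
    (case_id, drug_seq).  Malformed rows are logged and skipped; a missing
    mandatory file or unknown dialect is fatal.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    paths = {"DEMO": Path(demo_path), "DRUG": Path(drug_path), "REAC": Path(reac_path)}
    if ther_path is not None:
        paths["THER"] = Path(ther_path)
    for name, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"{name} file not found: {p}")

    prov: list[str] = []

    demo_rows, bad = _read_table(paths["DEMO"], dialect, DEMO_COLUMNS)
    prov.append(f"DEMO: {len(demo_rows)} rows read, {bad} malformed skipped")
    drug_rows, bad = _read_table(paths["DRUG"], dialect, DRUG_COLUMNS)
    prov.append(f"DRUG: {len(drug_rows)} rows read, {bad} malformed skipped")
    reac_rows, bad = _read_table(paths["REAC"], dialect, REAC_COLUMNS)
    prov.append(f"REAC: {len(reac_rows)} rows read, {bad} malformed skipped")
    if "THER" in paths:
        ther_rows, bad = _read_table(paths["THER"], dialect, THER_COLUMNS)
        prov.append(f"THER: {len(ther_rows)} rows read, {bad} malformed skipped")
    else:
        ther_rows = []
        prov.append("THER: not provided")

    demo = _build_demo(demo_rows)
    drugs = _build_drugs(drug_rows, ther_rows, synonyms)
    reactions = pd.DataFrame(reac_rows, columns=["case_id", "pt_name"])
    reactions = reactions.loc[reactions["pt_name"].str.strip() != ""].reset_index(drop=True)
    reactions["pt_name"] = reactions["pt_name"].str.strip()

    store = ReportStore(demo=demo, drugs=drugs, reactions=reactions, provenance=prov)
    store.check_integrity()
    return store


def _build_demo(rows: list[list[str]]) -> pd.DataFrame:
    records = []
    for caseid, caseversion, fda_dt, event_dt, sex, age, age_cod, wt, _wt_cod, occp, country, outc in rows:
        fda_date, _ = _parse_date(fda_dt)
        event_date, event_prec = _parse_date(event_dt)
        sex_l = {"M": "male", "F": "female"}.get(sex.upper(), "unknown")
        try:
            age_years = float(age) * _AGE_UNIT_YEARS.get(age_cod.upper(), 1.0)
        except ValueError:
            age_years = np.nan
        try:
            weight = float(wt)
        except ValueError:
            weight = np.nan
        outcomes = sorted(
            {OUTCOME_CODES[c.strip().upper()] for c in outc.split(",") if c.strip().upper() in OUTCOME_CODES}
        )
        year = int(fda_dt[:4]) if fda_dt[:4].isdigit() else (
            int(event_dt[:4]) if event_dt[:4].isdigit() else -1
        )
        try:
            version = int(caseversion)
        except ValueError:
            version = 0
        records.append(
            (caseid, version, fda_dt, fda_date, event_dt, event_date, event_prec,
             sex_l, age_years, weight, _OCCP_MAP.get(occp.upper(), "unknown"),
             country.upper() if country else "unknown", ",".join(outcomes), year)
        )
    demo = pd.DataFrame(
        records,
        columns=["case_id", "report_version", "fda_dt", "fda_date", "event_dt", "event_date",
                 "event_precision", "sex", "age_years", "weight_kg", "reporter", "country",
                 "outcomes", "report_year"],
    )
    demo["fda_date"] = pd.to_datetime(demo["fda_date"], errors="coerce")
    demo["event_date"] = pd.to_datetime(demo["event_date"], errors="coerce")
    return demo


def _build_drugs(
    rows: list[list[str]],
    ther_rows: list[list[str]],
    synonyms: dict[str, str] | None,
) -> pd.DataFrame:
    ther_map: dict[tuple[str, str], str] = {}
    for caseid, seq, start_dt in ther_rows:
        ther_map.setdefault((caseid, seq), start_dt)
    records = []
    valid_roles = {"PS", "SS", "C", "I"}
    for caseid, seq, role, name, indi in rows:
        role = role.upper()
        if role not in valid_roles:
            role = "C"
        start_dt = ther_map.get((caseid, seq), "")
        start_date, start_prec = _parse_date(start_dt)
        records.append(
            (caseid, int(seq) if seq.isdigit() else 0, role, name,
             normalize_drug_name(name, synonyms), indi, start_dt, start_date, start_prec)
        )
    drugs = pd.DataFrame(
        records,
        columns=["case_id", "drug_seq", "role", "verbatim_name", "canonical_name",
                 "indication_pt", "start_dt", "start_date", "start_precision"],
    )
    drugs["start_date"] = pd.to_datetime(drugs["start_date"], errors="coerce")
    return drugs


def deduplicate(store: ReportStore) -> ReportStore:
    """Keep one version per case: latest FDA receipt date, then highest
    report version, then last-seen input order (stable).

    Drug and reaction rows are keyed by case id (duplicate report versions
    differ only in their DEMO row), so dropping a discarded version never
    discards drug/reaction content of the surviving one.  Absent FDA dates
    sort lowest.
    """
    demo = store.demo.copy()
    n_in = len(demo)
    demo["_order"] = np.arange(n_in)
    demo["_fda_key"] = demo["fda_date"].fillna(pd.Timestamp.min)
    demo = demo.sort_values(["_fda_key", "report_version", "_order"], kind="stable")
    demo = demo.drop_duplicates("case_id", keep="last")
    demo = demo.sort_values("_order").drop(columns=["_order", "_fda_key"]).reset_index(drop=True)
    kept = set(demo["case_id"])
    out = ReportStore(
        demo=demo,
        drugs=store.drugs.loc[store.drugs["case_id"].isin(kept)].reset_index(drop=True),
        reactions=store.reactions.loc[store.reactions["case_id"].isin(kept)].reset_index(drop=True),
        provenance=list(store.provenance),
    )
    out.log(f"deduplicate: {n_in} report versions -> {len(demo)} unique cases")
    return out


def select_primary_suspect(store: ReportStore, target_canonical_name: str) -> set[str]:
    """Case ids whose drug entries name the target with role PS.

    Entries where the target appears only as secondary suspect (SS),
    concomitant (C) or interacting (I) do not qualify.
    """
    mask = (store.drugs["canonical_name"] == target_canonical_name) & (store.drugs["role"] == "PS")
    return set(store.drugs.loc[mask, "case_id"])


def apply_completeness_filter(store: ReportStore) -> ReportStore:
    """Drop cases lacking any drug entry or any reaction entry.

    Event-date completeness is *not* enforced here; incomplete onset dates
    only exclude a case from the time-to-onset analysis (see
    :mod:`faersig.tto`).
    """
    have_drugs = set(store.drugs["case_id"])
    have_reac = set(store.reactions["case_id"])
    cases = store.case_ids
    no_drugs = cases - have_drugs
    no_reac = cases - have_reac
    keep = cases & have_drugs & have_reac
    out = store.subset(keep)
    out.log(
        f"completeness: removed {len(no_drugs)} cases without drug entries, "
        f"{len(no_reac)} without reactions; {len(keep)} of {len(cases)} retained"
    )
    return out
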