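"""Shared fixtures: hand-built quarterly file sets and a seeded synthetic cohort."""

from __future__ import annotations

import csv
from pathlib import Path

import pytest

from faersig import ReportStore, apply_completeness_filter, deduplicate, read_quarter
from faersig.store import DEMO_COLUMNS, DRUG_COLUMNS, REAC_COLUMNS, THER_COLUMNS
from faersig.synth import SynthConfig, generate

_COLUMNS = {"DEMO": DEMO_COLUMNS, "DRUG": DRUG_COLUMNS, "REAC": REAC_COLUMNS, "THER": THER_COLUMNS}


def demo_row(caseid, version="1", fda="20240101", event="", sex="M", age="70",
             age_cod="YR", wt="", wt_cod="", occp="MD", country="US", outc=""):
    return [caseid, version, fda, event, sex, age, age_cod, wt, wt_cod, occp, country, outc]


def drug_row(caseid, seq="1", role="PS", name="ROFLUMILAST", indi=""):
    return [caseid, seq, role, name, indi]


def write_quarter(tmp_path: Path, demo, drug, reac, ther=(), dialect="simple-csv") -> dict[str, Path]:
    """Write header+rows tables in the requested dialect; returns file paths."""
    ext = "txt" if dialect == "faers-ascii" else "csv"
    tables = {"DEMO": demo, "DRUG": drug, "REAC": reac, "THER": ther}
    paths = {}
    for name, rows in tables.items():
        path = tmp_path / f"{name}.{ext}"
        if dialect == "faers-ascii":
            lines = ["$".join(_COLUMNS[name])]
            lines += ["$".join(str(v) for v in row) for row in rows]
            path.write_text("\n".join(lines) + "\n")
        else:
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(_COLUMNS[name])
                writer.writerows(rows)
        paths[name] = path
    return paths


def load_quarter(paths: dict[str, Path], dialect="simple-csv") -> ReportStore:
    return read_quarter(paths["DEMO"], paths["DRUG"], paths["REAC"], paths["THER"], dialect)


def store_from_outcome_mix(tmp_path: Path, mention_counts: dict, n_cases: int) -> ReportStore:
    """Build a store whose per-mention outcome counts equal ``mention_counts``.

    Reports counted under 'unknown' carry no outcome code.  Because a case
    can carry several codes, the surplus of mentions over cases is absorbed
    by pairing the two most frequent outcome labels on the same cases.
    """
    code_of = {"other": "OT", "hospitalization": "HO", "life-threatening": "LT",
               "disability": "DS", "death": "DE", "congenital anomaly": "CA",
               "required-intervention": "RI"}
    unknown = mention_counts.get("unknown", 0)
    coded = {k: v for k, v in mention_counts.items() if k != "unknown"}
    surplus = sum(coded.values()) - (n_cases - unknown)
    assert surplus >= 0
    (lab1, n1), (lab2, n2) = sorted(coded.items(), key=lambda kv: -kv[1])[:2]
    assert surplus <= min(n1, n2)
    rows, i = [], 0

    def add(n, outc):
        nonlocal i
        for _ in range(n):
            i += 1
            rows.append(demo_row(str(i), outc=outc))

    add(surplus, f"{code_of[lab1]},{code_of[lab2]}")
    add(n1 - surplus, code_of[lab1])
    add(n2 - surplus, code_of[lab2])
    for lab, n in coded.items():
        if lab not in (lab1, lab2):
            add(n, code_of[lab])
    add(unknown, "")
    assert len(rows) == n_cases
    paths = write_quarter(tmp_path, demo=rows,
                          drug=[drug_row(r[0]) for r in rows],
                          reac=[[r[0], "Nausea"] for r in rows])
    return load_quarter(paths)


@pytest.fixture(scope="session")
def synth_config() -> SynthConfig:
    return SynthConfig(seed=20240101, n_target_cases=500, n_background_cases=4000)


@pytest.fixture(scope="session")
def synth_dataset(synth_config):
    return generate(synth_config)


@pytest.fixture(scope="session")
def synth_files(synth_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("synth")
    return synth_dataset.write(out, dialect="simple-csv")


@pytest.fixture(scope="session")
def synth_store(synth_files) -> ReportStore:
    """The generated cohort after ingestion, dedup and completeness filter."""
    store = read_quarter(
        synth_files["DEMO"], synth_files["DRUG"], synth_files["REAC"], synth_files["THER"],
        "simple-csv",
    )
    return apply_completeness_filter(deduplicate(store))
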