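"""Seeded generator of FAERS-like quarterly data with a known answer key.

The generator emulates the structure of spontaneous-report data: DEMO rows
with report versions and partially missing demographics and dates, DRUG
rows with PS/SS/C/I roles and verbatim name variants, one-to-many REAC
rows, and THER therapy-start dates.  Target cases receive the target drug
as Primary Suspect (under a random synonym variant) and draw their
Preferred Terms from baseline reporting weights multiplied by injected
relative risks; onset intervals are Weibull draws added to the therapy
start date.  A :class:`GroundTruth` sidecar records the injected signals,
exact per-PT expected target counts, the generating Weibull parameters and
the duplicate-version map, so every downstream stage can be tested for
recovery.

All randomness flows from the single seed in :class:`SynthConfig`; a fixed
config yields byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contingency import PtSocMap

__all__ = ["SynthConfig", "GroundTruth", "SynthDataset", "generate", "DEFAULT_PT_SOC", "DEFAULT_BASELINE_WEIGHTS"]

#: toy PT -> SOC map covering the generated vocabulary
DEFAULT_PT_SOC = {
    "diarrhoea": "Gastrointestinal disorders",
    "nausea": "Gastrointestinal disorders",
    "vomiting": "Gastrointestinal disorders",
    "abdominal pain": "Gastrointestinal disorders",
    "frequent bowel movements": "Gastrointestinal disorders",
    "insomnia": "Psychiatric disorders",
    "anxiety": "Psychiatric disorders",
    "depression": "Psychiatric disorders",
    "suicidal ideation": "Psychiatric disorders",
    "nervousness": "Psychiatric disorders",
    "panic attack": "Psychiatric disorders",
    "headache": "Nervous system disorders",
    "dizziness": "Nervous system disorders",
    "tremor": "Nervous system disorders",
    "dyspnoea": "Respiratory, thoracic and mediastinal disorders",
    "cough": "Respiratory, thoracic and mediastinal disorders",
    "chronic obstructive pulmonary disease": "Respiratory, thoracic and mediastinal disorders",
    "sputum increased": "Respiratory, thoracic and mediastinal disorders",
    "death": "General disorders and administration site conditions",
    "fatigue": "General disorders and administration site conditions",
    "malaise": "General disorders and administration site conditions",
    "influenza like illness": "General disorders and administration site conditions",
    "weight decreased": "Investigations",
    "heart rate increased": "Investigations",
    "decreased appetite": "Metabolism and nutrition disorders",
    "back pain": "Musculoskeletal and connective tissue disorders",
    "arthralgia": "Musculoskeletal and connective tissue disorders",
    "tachycardia": "Cardiac disorders",
}

#: background reporting weights (relative frequency of each PT in the database)
DEFAULT_BASELINE_WEIGHTS = {
    "diarrhoea": 0.015, "nausea": 0.09, "vomiting": 0.05, "abdominal pain": 0.04,
    "frequent bowel movements": 0.004,
    "insomnia": 0.010, "anxiety": 0.03, "depression": 0.025, "suicidal ideation": 0.0025,
    "nervousness": 0.006, "panic attack": 0.005,
    "headache": 0.09, "dizziness": 0.06, "tremor": 0.015,
    "dyspnoea": 0.06, "cough": 0.03, "chronic obstructive pulmonary disease": 0.0015,
    "sputum increased": 0.002,
    "death": 0.07, "fatigue": 0.09, "malaise": 0.04, "influenza like illness": 0.008,
    "weight decreased": 0.004, "heart rate increased": 0.01,
    "decreased appetite": 0.005, "back pain": 0.04, "arthralgia": 0.035, "tachycardia": 0.012,
}

#: injected drug-event associations: PT -> relative reporting risk for target cases
DEFAULT_INJECTED_SIGNALS = {
    "diarrhoea": 5.0,
    "weight decreased": 8.0,
    "insomnia": 6.5,
    "suicidal ideation": 8.0,
    "decreased appetite": 6.5,
    "chronic obstructive pulmonary disease": 25.0,
}

_BACKGROUND_DRUGS = (
    "METFORMIN", "LISINOPRIL", "ATORVASTATIN", "OMEPRAZOLE", "SALBUTAMOL",
    "PREDNISONE", "TIOTROPIUM", "AMOXICILLIN", "WARFARIN", "SERTRALINE",
)

_INDICATIONS = ("Chronic obstructive pulmonary disease", "Psoriasis", "Emphysema", "Asthma", "")
_INDICATION_P = (0.75, 0.055, 0.02, 0.02, 0.155)


@dataclass
class SynthConfig:
    """Generator parameters; defaults emulate a roflumilast-like cohort.

    Demographic, reporter, country and outcome distributions default to the
    marginal frequencies typical of such a cohort; onset intervals come
    from Weibull(shape 0.573, scale 38.653 d), an early-failure pattern.
    ``missing_date_rate`` applies independently to the event and therapy
    start dates, so roughly (1-rate)^2 of target cases carry a computable
    onset interval.
    """

    seed: int = 0
    n_target_cases: int = 3140
    n_background_cases: int = 20000
    target_drug: str = "roflumilast"
    target_variants: tuple = ("ROFLUMILAST", "DALIRESP", "Daxas", "roflumilast  ")
    background_drugs: tuple = _BACKGROUND_DRUGS
    pt_soc: dict = field(default_factory=lambda: dict(DEFAULT_PT_SOC))
    baseline_weights: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_WEIGHTS))
    injected_signals: dict = field(default_factory=lambda: dict(DEFAULT_INJECTED_SIGNALS))
    reactions_per_case_mean: float = 2.5
    duplicate_rate: float = 0.08
    missing_date_rate: float = 0.48
    partial_date_rate: float = 0.05
    inconsistent_date_rate: float = 0.02
    background_target_noise_rate: float = 0.02
    tto_shape_beta: float = 0.573
    tto_scale_alpha_days: float = 38.653
    year_range: tuple = (2011, 2024)
    sex_probs: dict = field(default_factory=lambda: {"M": 0.459, "F": 0.407, "": 0.134})
    reporter_probs: dict = field(default_factory=lambda: {"CN": 0.347, "MD": 0.239, "PH": 0.029, "OT": 0.288, "": 0.097})
    country_probs: dict = field(default_factory=lambda: {"US": 0.781, "DE": 0.173, "CA": 0.008, "KR": 0.007, "DK": 0.003, "": 0.028})
    outcome_probs: dict = field(default_factory=lambda: {
        "OT": 0.26, "HO": 0.236, "LT": 0.030, "DS": 0.012, "DE": 0.199, "CA": 0.0003, "RI": 0.066,
    })
    age_bin_probs: dict = field(default_factory=lambda: {
        "<18": 0.002, "18-44": 0.006, "45-64": 0.135, "65-75": 0.228, ">75": 0.201, "unknown": 0.428,
    })
    weight_bin_probs: dict = field(default_factory=lambda: {
        "<50": 0.029, "50-100": 0.220, ">100": 0.026, "unknown": 0.725,
    })

    def __post_init__(self):
        if not self.pt_soc or not self.baseline_weights:
            raise ValueError("PT vocabulary must be non-empty")
        if set(self.baseline_weights) - set(self.pt_soc):
            raise ValueError("every weighted PT needs a SOC mapping")
        for pt, rr in self.injected_signals.items():
            if pt not in self.baseline_weights:
                raise ValueError(f"injected signal PT {pt!r} not in the vocabulary")
            if rr <= 0:
                raise ValueError(f"relative risk for {pt!r} must be > 0")
        for name in ("duplicate_rate", "missing_date_rate", "partial_date_rate",
                     "inconsistent_date_rate", "background_target_noise_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.reactions_per_case_mean <= 0:
            raise ValueError("reactions_per_case_mean must be positive")
        if min(self.tto_shape_beta, self.tto_scale_alpha_days) <= 0:
            raise ValueError("Weibull parameters must be positive")


@dataclass
class GroundTruth:
    """Answer key for a generated dataset."""

    injected_signals: dict
    expected_target_pt_counts: dict  # PT -> expected number of target cases reporting it
    expected_background_pt_counts: dict
    tto_shape_beta: float
    tto_scale_alpha_days: float
    duplicate_versions: dict  # case_id -> list of emitted report versions
    n_target_cases: int
    n_background_cases: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Poisson(lam) conditioned on k >= 1."""
    k = rng.poisson(lam, size)
    while True:
        zero = k == 0
        if not zero.any():
            return k
        k[zero] = rng.poisson(lam, int(zero.sum()))


def _inclusion_probability(w: np.ndarray, lam: float) -> np.ndarray:
    """P(PT i appears in a case) when k ~ truncated Poisson(lam) PTs are
    drawn with replacement with weights w and collapsed to distinct terms.

    Uses the truncated-Poisson pgf: E[s^k] = (e^{lam(s-1)} - e^{-lam}) / (1 - e^{-lam}).
    """
    s = 1.0 - w
    pgf = (np.exp(lam * (s - 1.0)) - math.exp(-lam)) / (1.0 - math.exp(-lam))
    return 1.0 - pgf


def _target_weights(base_w: np.ndarray, rr: np.ndarray) -> np.ndarray:
    """Target-arm PT draw weights: baseline weights multiplied by the
    injected relative risks.

    Injected PTs (rr != 1) keep the absolute share base_w*rr of the
    baseline total, so their per-draw share rises by exactly rr; only the
    non-injected PTs are rescaled to absorb the difference.  If the
    injected mass exhausts the total, everything falls back to plain
    proportional renormalisation.
    """
    injected = rr != 1.0
    total = base_w.sum()
    raw = base_w * rr
    injected_mass = raw[injected].sum()
    rest_mass = base_w[~injected].sum()
    if injected_mass < total and rest_mass > 0:
        w = raw.copy()
        w[~injected] = base_w[~injected] * (total - injected_mass) / rest_mass
    else:
        w = raw
    return w / w.sum()


def _fmt_date(ts: pd.Timestamp, precision: str = "day") -> str:
    if precision == "day":
        return f"{ts.year:04d}{ts.month:02d}{ts.day:02d}"
    if precision == "month":
        return f"{ts.year:04d}{ts.month:02d}"
    return f"{ts.year:04d}"


@dataclass
class SynthDataset:
    """Generated file tables (string-typed, file schema) plus the answer key."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    ground_truth: GroundTruth
    pt_soc_map: PtSocMap

    def write(self, out_dir: str | Path, dialect: str = "simple-csv") -> dict[str, Path]:
        """Emit the four tables, the PT->SOC map and the answer key.

        Returns the paths keyed by table name.  The faers-ascii dialect
        writes "$"-delimited .txt files, simple-csv writes .csv.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        tables = {"DEMO": self.demo, "DRUG": self.drug, "REAC": self.reac, "THER": self.ther}
        for name, frame in tables.items():
            if dialect == "faers-ascii":
                path = out / f"{name}.txt"
                lines = ["$".join(frame.columns)]
                lines += ["$".join(map(str, row)) for row in frame.itertuples(index=False)]
                path.write_text("\n".join(lines) + "\n")
            elif dialect == "simple-csv":
                path = out / f"{name}.csv"
                frame.to_csv(path, index=False)
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            paths[name] = path
        soc_frame = pd.DataFrame(
            sorted(self.pt_soc_map._map.items()), columns=["pt", "soc"]
        )
        soc_frame.to_csv(out / "pt_soc_map.csv", index=False)
        paths["PT_SOC"] = out / "pt_soc_map.csv"
        self.ground_truth.to_json(out / "ground_truth.json")
        paths["GROUND_TRUTH"] = out / "ground_truth.json"
        return paths


def generate(config: SynthConfig) -> SynthDataset:
    """Generate one synthetic quarterly dataset from a config.

    Target cases get the target drug as PS under a random verbatim variant;
    a small fraction of background cases carry the target in a concomitant
    role (and must *not* be selected by a PS filter).  Duplicate report
    versions differ only in their DEMO row (earlier FDA date, lower
    version), never in drugs or reactions.
    """
    rng = np.random.default_rng(config.seed)
    pts = sorted(config.baseline_weights)
    base_w = np.array([config.baseline_weights[pt] for pt in pts], dtype=float)
    rr = np.array([config.injected_signals.get(pt, 1.0) for pt in pts], dtype=float)
    w_background = base_w / base_w.sum()
    w_target = _target_weights(base_w, rr)
    lam = config.reactions_per_case_mean

    n_total = config.n_target_cases + config.n_background_cases
    is_target = np.zeros(n_total, dtype=bool)
    is_target[: config.n_target_cases] = True
    case_ids = [f"C{i + 1:07d}" for i in range(n_total)]

    # --- reactions -------------------------------------------------------
    k_draws = _truncated_poisson(rng, lam, n_total)
    reac_rows: list[tuple[str, str]] = []
    target_pt_hits = {pt: 0 for pt in pts}
    background_pt_hits = {pt: 0 for pt in pts}
    for cid, tgt, k in zip(case_ids, is_target, k_draws):
        w = w_target if tgt else w_background
        chosen = np.unique(rng.choice(len(pts), size=k, p=w))
        hits = target_pt_hits if tgt else background_pt_hits
        for idx in chosen:
            pt = pts[idx]
            hits[pt] += 1
            reac_rows.append((cid, pt))

    # --- dates -----------------------------------------------------------
    y0, y1 = config.year_range
    years = rng.integers(y0, y1 + 1, n_total)
    day_of_year = rng.integers(0, 365, n_total)
    fda_dates = pd.to_datetime([f"{y}-01-01" for y in years]) + pd.to_timedelta(day_of_year, unit="D")
    start_offsets = rng.integers(30, 400, n_total)  # therapy began before the report
    start_dates = fda_dates - pd.to_timedelta(start_offsets, unit="D")
    # calendar-day difference: an onset w days after the start lands on the
    # date floor(w) days later, so integer TTOs are floored, not rounded
    onset_days = np.floor(
        config.tto_scale_alpha_days * rng.weibull(config.tto_shape_beta, n_total)
    ).astype(int)
    event_dates = start_dates + pd.to_timedelta(onset_days, unit="D")
    inconsistent = rng.random(n_total) < config.inconsistent_date_rate
    back_days = rng.integers(1, 30, n_total)
    event_dates = event_dates.where(
        ~inconsistent, start_dates - pd.to_timedelta(back_days, unit="D")
    )
    event_missing = rng.random(n_total) < config.missing_date_rate
    event_partial = rng.random(n_total) < config.partial_date_rate
    start_missing = rng.random(n_total) < config.missing_date_rate

    # --- demographics ----------------------------------------------------
    def draw_cat(probs: dict, size: int) -> np.ndarray:
        labels = list(probs)
        p = np.array([probs[k] for k in labels], dtype=float)
        return rng.choice(labels, size=size, p=p / p.sum())

    sexes = draw_cat(config.sex_probs, n_total)
    reporters = draw_cat(config.reporter_probs, n_total)
    countries = draw_cat(config.country_probs, n_total)
    age_bins = draw_cat(config.age_bin_probs, n_total)
    weight_bins = draw_cat(config.weight_bin_probs, n_total)
    age_edges = {"<18": (2, 18), "18-44": (18, 45), "45-64": (45, 65), "65-75": (65, 75), ">75": (75, 95)}
    weight_edges = {"<50": (38, 50), "50-100": (50, 100), ">100": (100, 150)}
    ages = np.array([
        "" if b == "unknown" else str(int(rng.integers(*age_edges[b]))) for b in age_bins
    ])
    weights = np.array([
        "" if b == "unknown" else str(int(rng.integers(*weight_edges[b]))) for b in weight_bins
    ])
    outc_codes = list(config.outcome_probs)
    outc_draw = rng.random((n_total, len(outc_codes))) < np.array(
        [config.outcome_probs[c] for c in outc_codes]
    )
    outcomes = [",".join(c for c, hit in zip(outc_codes, row) if hit) for row in outc_draw]

    # --- DEMO rows (plus duplicate versions) -----------------------------
    n_dup = int(round(config.duplicate_rate * n_total))
    dup_idx = set(rng.choice(n_total, size=n_dup, replace=False).tolist()) if n_dup else set()
    dup_back_days = rng.integers(10, 200, n_total)
    demo_rows = []
    duplicate_versions: dict[str, list[int]] = {}
    for i, cid in enumerate(case_ids):
        if event_missing[i]:
            event_str = ""
        elif event_partial[i]:
            event_str = _fmt_date(event_dates[i], "month")
        else:
            event_str = _fmt_date(event_dates[i])
        latest_version = 2 if i in dup_idx else 1
        row = (
            cid, str(latest_version), _fmt_date(fda_dates[i]), event_str, sexes[i],
            ages[i], "YR" if ages[i] else "", weights[i], "KG" if weights[i] else "",
            reporters[i], countries[i], outcomes[i],
        )
        if i in dup_idx:
            old = (
                cid, "1", _fmt_date(fda_dates[i] - pd.Timedelta(days=int(dup_back_days[i]))),
                event_str, sexes[i], ages[i], "YR" if ages[i] else "", weights[i],
                "KG" if weights[i] else "", reporters[i], countries[i], outcomes[i],
            )
            demo_rows.append(old)
            duplicate_versions[cid] = [1, 2]
        demo_rows.append(row)
    demo = pd.DataFrame(
        demo_rows,
        columns=["caseid", "caseversion", "fda_dt", "event_dt", "sex", "age", "age_cod",
                 "wt", "wt_cod", "occp_cod", "occr_country", "outc_cod"],
    )

    # --- DRUG / THER rows ------------------------------------------------
    drug_rows, ther_rows = [], []
    variant_pick = rng.integers(0, len(config.target_variants), n_total)
    bg_pick = rng.integers(0, len(config.background_drugs), n_total)
    conco_pick = rng.integers(0, len(config.background_drugs), n_total)
    has_conco = rng.random(n_total) < 0.5
    bg_has_target = rng.random(n_total) < config.background_target_noise_rate
    indi_pick = rng.choice(len(_INDICATIONS), size=n_total, p=np.array(_INDICATION_P))
    for i, cid in enumerate(case_ids):
        if is_target[i]:
            primary = config.target_variants[variant_pick[i]]
            indication = _INDICATIONS[indi_pick[i]]
        else:
            primary = config.background_drugs[bg_pick[i]]
            indication = ""
        drug_rows.append((cid, "1", "PS", primary, indication))
        ther_rows.append((cid, "1", "" if start_missing[i] else _fmt_date(start_dates[i])))
        if has_conco[i]:
            drug_rows.append((cid, "2", "C", config.background_drugs[conco_pick[i]], ""))
        if (not is_target[i]) and bg_has_target[i]:
            drug_rows.append((cid, "3", "C", config.target_variants[variant_pick[i]], ""))
    drug = pd.DataFrame(drug_rows, columns=["caseid", "drug_seq", "role_cod", "drugname", "indi_pt"])
    ther = pd.DataFrame(ther_rows, columns=["caseid", "dsg_drug_seq", "start_dt"])
    reac = pd.DataFrame(reac_rows, columns=["caseid", "pt"])

    # --- ground truth ----------------------------------------------------
    q_target = _inclusion_probability(w_target, lam)
    q_background = _inclusion_probability(w_background, lam)
    truth = GroundTruth(
        injected_signals=dict(config.injected_signals),
        expected_target_pt_counts={pt: float(config.n_target_cases * q) for pt, q in zip(pts, q_target)},
        expected_background_pt_counts={pt: float(config.n_background_cases * q) for pt, q in zip(pts, q_background)},
        tto_shape_beta=config.tto_shape_beta,
        tto_scale_alpha_days=config.tto_scale_alpha_days,
        duplicate_versions=duplicate_versions,
        n_target_cases=config.n_target_cases,
        n_background_cases=config.n_background_cases,
    )
    return SynthDataset(
        demo=demo, drug=drug, reac=reac, ther=ther,
        ground_truth=truth, pt_soc_map=PtSocMap(config.pt_soc),
    )
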