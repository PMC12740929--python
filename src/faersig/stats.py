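"""Disproportionality statistics for 2x2 drug-event contingency tables.

Four classical pharmacovigilance estimators, in their closed-form (unshrunk)
versions, all computed from the cells a, b, c, d (N = a+b+c+d):

    ROR  = ad / bc,          95% CI = exp(ln ROR +/- 1.96*SE)
    PRR  = [a/(a+b)] / [c/(c+d)]
    chi2 = (ad - bc)^2 * N / [(a+b)(c+d)(a+c)(b+d)]   (no continuity correction)
    IC   = log2[ a*N / ((a+c)(a+b)) ],   IC025  = IC - 1.96*SE/ln 2
    EBGM = a*N / ((a+c)(a+b)),           EBGM05 = exp(ln EBGM - 1.96*SE)

with the shared log-scale standard error SE = sqrt(1/a + 1/b + 1/c + 1/d).
IC and EBGM here are the observed-over-expected ratio on log2 and natural
scales, so IC == log2(EBGM) identically; full Bayesian BCPNN posteriors and
MGPS gamma-Poisson shrinkage are deliberately out of scope.  A table with
any zero cell receives the Haldane-Anscombe +0.5 correction on all four
cells before estimation.

A term is flagged as a signal only when every criterion holds jointly:
n >= 3 reports, ROR lower CI > 1, PRR >= 2 with chi2 >= 4, IC025 > 0 and
EBGM05 > 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .contingency import ContingencyTable

__all__ = [
    "SignalCriteria",
    "SignalMetrics",
    "ror_estimate",
    "prr_estimate",
    "bcpnn_ic",
    "mgps_ebgm",
    "compute_metrics",
    "evaluate_signal",
    "rank_signals",
    "metrics_to_frame",
]

Z95 = 1.96
Z90 = 1.645  # one-sided 5th percentile, optional EBGM05 convention


@dataclass(frozen=True)
class SignalCriteria:
    """Joint signal thresholds; defaults are the standard published criteria."""

    min_n: int = 3
    ror_low_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not math.isfinite(v):
                raise ValueError(f"criterion {name} must be finite, got {v!r}")


@dataclass
class SignalMetrics:
    term: str
    level: str
    n: int
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    zero_corrected: bool = False
    is_signal: bool = False
    failed_criteria: list = field(default_factory=list)


def _corrected_cells(table: ContingencyTable) -> tuple[float, float, float, float, bool]:
    """Haldane-Anscombe: +0.5 on every cell if any cell is zero."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == b == c == d == 0:
        raise ValueError(f"empty table for {table.term!r}")
    if min(a, b, c, d) == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return a, b, c, d, False


def _log_se(a: float, b: float, c: float, d: float) -> float:
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def ror_estimate(table: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with its 95% CI; returns (ror, low, high)."""
    a, b, c, d, _ = _corrected_cells(table)
    ror = (a * d) / (b * c)
    half = Z95 * _log_se(a, b, c, d)
    return ror, ror * math.exp(-half), ror * math.exp(half)


def prr_estimate(table: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and its chi-square; returns (prr, chi2)."""
    a, b, c, d, _ = _corrected_cells(table)
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    chi2 = ((a * d - b * c) ** 2 * n) / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, chi2


def bcpnn_ic(table: ContingencyTable) -> tuple[float, float]:
    """Information component and its lower bound; returns (ic, ic025).

    IC025 is IC minus 1.96 log-scale standard errors expressed in log2
    units (IC - 2SD convention), which keeps it defined for IC <= 0.
    """
    a, b, c, d, _ = _corrected_cells(table)
    n = a + b + c + d
    ic = math.log2(a * n / ((a + c) * (a + b)))
    ic025 = ic - Z95 * _log_se(a, b, c, d) / math.log(2)
    return ic, ic025


def mgps_ebgm(table: ContingencyTable, strict_5th: bool = False) -> tuple[float, float]:
    """Observed/expected ratio (unshrunk EBGM) and lower bound.

    ``strict_5th`` switches the lower bound from the 1.96 (two-sided 95%)
    convention to a one-sided 5th percentile (1.645).
    """
    a, b, c, d, _ = _corrected_cells(table)
    n = a + b + c + d
    ebgm = a * n / ((a + c) * (a + b))
    z = Z90 if strict_5th else Z95
    ebgm05 = math.exp(math.log(ebgm) - z * _log_se(a, b, c, d))
    return ebgm, ebgm05


def compute_metrics(
    table: ContingencyTable,
    criteria: SignalCriteria | None = None,
    strict_5th: bool = False,
) -> SignalMetrics:
    """All four estimators plus the signal verdict for one table."""
    if criteria is None:
        criteria = SignalCriteria()
    ror, lo, hi = ror_estimate(table)
    prr, chi2 = prr_estimate(table)
    ic, ic025 = bcpnn_ic(table)
    ebgm, ebgm05 = mgps_ebgm(table, strict_5th=strict_5th)
    corrected = min(table.a, table.b, table.c, table.d) == 0
    m = SignalMetrics(
        term=table.term, level=table.level, n=int(table.a),
        ror=ror, ror_low=lo, ror_high=hi, prr=prr, chi2=chi2,
        ic=ic, ic025=ic025, ebgm=ebgm, ebgm05=ebgm05, zero_corrected=corrected,
    )
    m.is_signal, m.failed_criteria = evaluate_signal(m, criteria)
    return m


def evaluate_signal(metrics: SignalMetrics, criteria: SignalCriteria | None = None) -> tuple[bool, list[str]]:
    """Check the joint criteria; returns (is_signal, names of failed clauses)."""
    if criteria is None:
        criteria = SignalCriteria()
    failed = []
    if metrics.n < criteria.min_n:
        failed.append("min_n")
    if not metrics.ror_low > criteria.ror_low_gt:
        failed.append("ror_low")
    if not metrics.prr >= criteria.prr_ge:
        failed.append("prr")
    if not metrics.chi2 >= criteria.chi2_ge:
        failed.append("chi2")
    if not metrics.ic025 > criteria.ic025_gt:
        failed.append("ic025")
    if not metrics.ebgm05 > criteria.ebgm05_gt:
        failed.append("ebgm05")
    return (not failed), failed


def rank_signals(metrics_list: list[SignalMetrics], key: str = "frequency") -> pd.DataFrame:
    """Order signal metrics: 'frequency' = descending n, 'strength' =
    descending EBGM05; ties broken alphabetically by term."""
    if key == "frequency":
        sort_col = "n"
    elif key == "strength":
        sort_col = "EBGM05"
    else:
        raise ValueError(f"unknown ranking key {key!r}; expected 'frequency' or 'strength'")
    frame = metrics_to_frame(metrics_list)
    if frame.empty:
        return frame
    return (
        frame.sort_values([sort_col, "term"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )


def metrics_to_frame(metrics_list: list[SignalMetrics]) -> pd.DataFrame:
    """Tabular export mirroring the usual signal-table layout."""
    cols = ["term", "level", "n", "ROR", "ROR_low", "ROR_high", "PRR", "chi2",
            "IC", "IC025", "EBGM", "EBGM05", "is_signal", "failed_criteria"]
    rows = [
        (m.term, m.level, m.n, m.ror, m.ror_low, m.ror_high, m.prr, m.chi2,
         m.ic, m.ic025, m.ebgm, m.ebgm05, m.is_signal, ";".join(m.failed_criteria))
        for m in metrics_list
    ]
    return pd.DataFrame(rows, columns=cols)
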