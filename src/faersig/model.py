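"""Model/results interface for case/non-case disproportionality analysis.

:class:`DisproportionalityAnalysis` is constructed from a deduplicated
report store and a target drug; ``fit()`` builds the per-PT (and, when a
PT->SOC map is supplied, per-SOC) 2x2 tables, computes ROR, PRR/chi2, IC
and EBGM with their lower bounds, applies the joint signal criteria and
returns a :class:`DisproportionalityResults` carrying the full metric
tables, ranking helpers and a text summary.
"""

from __future__ import annotations

import pandas as pd

from .contingency import PtSocMap, aggregate_soc, build_pt_tables
from .stats import SignalCriteria, SignalMetrics, compute_metrics, metrics_to_frame, rank_signals
from .store import ReportStore, select_primary_suspect

__all__ = ["DisproportionalityAnalysis", "DisproportionalityResults"]


class DisproportionalityAnalysis:
    """Case/non-case disproportionality model for one target drug.

    Parameters
    ----------
    store : ReportStore
        Deduplicated report store; every case not in the target set forms
        the background.
    target : str
        Canonical (normalised) drug name; target cases are those naming it
        as Primary Suspect.
    pt_soc_map : PtSocMap, optional
        Enables the SOC-level aggregation.
    criteria : SignalCriteria, optional
        Signal thresholds (defaults: n>=3, ROR_low>1, PRR>=2 & chi2>=4,
        IC025>0, EBGM05>2).
    """

    def __init__(
        self,
        store: ReportStore,
        target: str,
        pt_soc_map: PtSocMap | None = None,
        criteria: SignalCriteria | None = None,
        target_case_ids: set[str] | None = None,
    ):
        self.store = store
        self.target = target
        self.pt_soc_map = pt_soc_map
        self.criteria = criteria or SignalCriteria()
        self.target_case_ids = (
            target_case_ids if target_case_ids is not None else select_primary_suspect(store, target)
        )

    def fit(self) -> "DisproportionalityResults":
        pt_tables = build_pt_tables(self.store, self.target_case_ids)
        pt_metrics = [compute_metrics(t, self.criteria) for t in pt_tables]
        soc_metrics: list[SignalMetrics] = []
        if self.pt_soc_map is not None:
            soc_tables = aggregate_soc(pt_tables, self.pt_soc_map)
            soc_metrics = [compute_metrics(t, self.criteria) for t in soc_tables]
        return DisproportionalityResults(self, pt_metrics, soc_metrics)


class DisproportionalityResults:
    """Fitted disproportionality metrics at PT and (optionally) SOC level."""

    def __init__(self, model: DisproportionalityAnalysis, pt_metrics, soc_metrics):
        self.model = model
        self.pt_metrics: list[SignalMetrics] = pt_metrics
        self.soc_metrics: list[SignalMetrics] = soc_metrics

    @property
    def pt_table(self) -> pd.DataFrame:
        return metrics_to_frame(self.pt_metrics)

    @property
    def soc_table(self) -> pd.DataFrame:
        return metrics_to_frame(self.soc_metrics)

    def signals(self, level: str = "PT") -> pd.DataFrame:
        """Only the terms meeting every signal criterion, most frequent first."""
        metrics = self.pt_metrics if level.upper() == "PT" else self.soc_metrics
        return rank_signals([m for m in metrics if m.is_signal], key="frequency")

    def rank(self, key: str = "frequency", level: str = "PT", signals_only: bool = True) -> pd.DataFrame:
        metrics = self.pt_metrics if level.upper() == "PT" else self.soc_metrics
        if signals_only:
            metrics = [m for m in metrics if m.is_signal]
        return rank_signals(metrics, key=key)

    def signal_soc_distribution(self) -> pd.DataFrame:
        """How the flagged PTs distribute over SOCs (count of signal PT
        categories per SOC and their share of all signal PTs)."""
        if self.model.pt_soc_map is None:
            raise ValueError("signal_soc_distribution requires a PT->SOC map")
        flagged = [m.term for m in self.pt_metrics if m.is_signal]
        socs = pd.Series([self.model.pt_soc_map[pt] for pt in flagged], dtype=object)
        counts = socs.value_counts()
        total = int(counts.sum())
        return pd.DataFrame(
            {
                "soc": counts.index,
                "n_signal_pts": counts.to_numpy(),
                "percent": (100.0 * counts / total).round(2).to_numpy() if total else [],
            }
        ).reset_index(drop=True)

    def summary(self) -> str:
        n_sig = sum(m.is_signal for m in self.pt_metrics)
        lines = [
            "Disproportionality analysis",
            "===========================",
            f"target drug:        {self.model.target}",
            f"target cases (PS):  {len(self.model.target_case_ids)}",
            f"background cases:   {len(self.model.store) - len(self.model.target_case_ids)}",
            f"PTs evaluated:      {len(self.pt_metrics)}",
            f"PT signals:         {n_sig}",
        ]
        top = self.signals("PT").head(10)
        if not top.empty:
            lines.append("")
            lines.append("top signals by frequency:")
            cols = ["term", "n", "ROR", "ROR_low", "ROR_high", "PRR", "chi2", "IC025", "EBGM05"]
            lines.append(top[cols].round(2).to_string(index=False))
        return "\n".join(lines)
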