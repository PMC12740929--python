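"""Disproportionality estimators: frozen oracles, identities, criteria, ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faersig import (
    ContingencyTable,
    SignalCriteria,
    bcpnn_ic,
    compute_metrics,
    evaluate_signal,
    mgps_ebgm,
    prr_estimate,
    rank_signals,
    ror_estimate,
)


def table(a, b, c, d, term="t", level="PT"):
    return ContingencyTable(term, level, a, b, c, d)


def naive_metrics(a, b, c, d):
    """Independent re-implementation of the four printed formulas.

    Deliberately written from scratch (no shared helpers) as the oracle for
    equivalence testing.
    """
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n = a + b + c + d
    se = (1 / a + 1 / b + 1 / c + 1 / d) ** 0.5
    ror = (a * d) / (b * c)
    out = {
        "ror": ror,
        "ror_low": math.exp(math.log(ror) - 1.96 * se),
        "ror_high": math.exp(math.log(ror) + 1.96 * se),
        "prr": (a / (a + b)) / (c / (c + d)),
        "chi2": ((a * d - b * c) ** 2 * n) / ((a + b) * (c + d) * (a + c) * (b + d)),
        "ic": math.log(a * n / ((a + c) * (a + b)), 2),
        "ebgm": a * n / ((a + c) * (a + b)),
    }
    out["ic025"] = out["ic"] - 1.96 * se / math.log(2)
    out["ebgm05"] = math.exp(math.log(out["ebgm"]) - 1.96 * se)
    return out


DERIVED = table(20, 80, 10, 890)  # frozen worked example


class TestEstimators:
    def test_null_table_is_exactly_null(self):
        null = table(5, 5, 5, 5)
        ror, lo, hi = ror_estimate(null)
        assert ror == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)  # CI symmetric about 1 on the log scale
        prr, chi2 = prr_estimate(null)
        assert (prr, chi2) == (pytest.approx(1.0), pytest.approx(0.0))
        ic, ic025 = bcpnn_ic(null)
        assert ic == pytest.approx(0.0)
        assert ic025 < 0
        ebgm, _ = mgps_ebgm(null)
        assert ebgm == pytest.approx(1.0)

    def test_derived_table_frozen_values(self):
        ror, lo, hi = ror_estimate(DERIVED)
        assert ror == pytest.approx(22.25)
        assert lo == pytest.approx(10.0695287, rel=1e-6)
        assert hi == pytest.approx(49.1644162, rel=1e-6)
        prr, chi2 = prr_estimate(DERIVED)
        assert prr == pytest.approx(18.0)
        assert chi2 == pytest.approx(110.3474609, rel=1e-6)
        ic, ic025 = bcpnn_ic(DERIVED)
        assert ic == pytest.approx(2.7369656, rel=1e-6)
        assert ic025 == pytest.approx(1.5931564, rel=1e-6)
        ebgm, ebgm05 = mgps_ebgm(DERIVED)
        assert ebgm == pytest.approx(20 * 1000 / (30 * 100))
        assert ebgm05 == pytest.approx(3.0170873, rel=1e-6)

    def test_haldane_correction_applied_on_zero_cell(self):
        corrected = table(0, 10, 10, 10)
        ror, _, _ = ror_estimate(corrected)
        assert ror == pytest.approx(0.5 * 10.5 / (10.5 * 10.5))
        assert compute_metrics(corrected).zero_corrected

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError, match="empty table"):
            ror_estimate(table(0, 0, 0, 0))

    def test_chi2_invariant_under_transposition(self):
        t = table(7, 13, 29, 151)
        swapped_rows = table(29, 151, 7, 13)
        swapped_cols = table(13, 7, 151, 29)
        _, chi2 = prr_estimate(t)
        assert prr_estimate(swapped_rows)[1] == pytest.approx(chi2)
        assert prr_estimate(swapped_cols)[1] == pytest.approx(chi2)

    def test_strict_5th_percentile_option_is_larger(self):
        _, default = mgps_ebgm(DERIVED)
        _, strict = mgps_ebgm(DERIVED, strict_5th=True)
        assert strict > default  # 1.645 < 1.96 sigma below the point estimate


cells = st.integers(min_value=1, max_value=2000)


@settings(derandomize=True, max_examples=200)
@given(cells, cells, cells, cells)
def test_ic_is_log2_ebgm_identically(a, b, c, d):
    ic, _ = bcpnn_ic(table(a, b, c, d))
    ebgm, _ = mgps_ebgm(table(a, b, c, d))
    assert ic == pytest.approx(math.log2(ebgm), abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(cells, cells, cells, cells)
def test_cross_metric_concordance(a, b, c, d):
    """For all-positive tables: ROR>1 iff PRR>1 iff IC>0 iff EBGM>1."""
    t = table(a, b, c, d)
    ror = ror_estimate(t)[0]
    prr = prr_estimate(t)[0]
    ic = bcpnn_ic(t)[0]
    ebgm = mgps_ebgm(t)[0]
    signs = {np.sign(round(ror - 1, 12)), np.sign(round(prr - 1, 12)),
             np.sign(round(ic, 12)), np.sign(round(ebgm - 1, 12))}
    assert len(signs) == 1


def test_oracle_equivalence_on_random_tables():
    """All four statistics match the independent oracle to 1e-12 relative
    error on 1,000 random small tables (zero cells included)."""
    rng = np.random.default_rng(42)
    draws = rng.integers(0, 500, size=(1000, 4))
    draws[draws.sum(axis=1) == 0] += 1
    for a, b, c, d in draws:
        m = compute_metrics(table(int(a), int(b), int(c), int(d)))
        expected = naive_metrics(int(a), int(b), int(c), int(d))
        for key, got in [("ror", m.ror), ("ror_low", m.ror_low), ("ror_high", m.ror_high),
                         ("prr", m.prr), ("chi2", m.chi2), ("ic", m.ic), ("ic025", m.ic025),
                         ("ebgm", m.ebgm), ("ebgm05", m.ebgm05)]:
            assert got == pytest.approx(expected[key], rel=1e-12, abs=1e-12), key


class TestSignalCriteria:
    def test_derived_table_is_a_signal(self):
        m = compute_metrics(DERIVED)
        assert m.is_signal
        assert m.failed_criteria == []

    def test_two_reports_fail_only_min_n(self):
        strong = table(2, 1, 1, 10000)
        m = compute_metrics(strong)
        assert not m.is_signal
        assert m.failed_criteria == ["min_n"]

    def test_null_table_fails_every_distributional_clause(self):
        m = compute_metrics(table(5, 5, 5, 5))
        assert not m.is_signal
        assert set(m.failed_criteria) == {"ror_low", "prr", "chi2", "ic025", "ebgm05"}

    def test_criteria_monotone_in_min_n(self):
        m = compute_metrics(DERIVED, SignalCriteria(min_n=21))
        assert m.failed_criteria == ["min_n"]

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(ValueError):
            SignalCriteria(prr_ge=float("nan"))


class TestRankSignals:
    def _metrics(self, specs):
        return [compute_metrics(table(a, b, c, d, term=name)) for name, a, b, c, d in specs]

    def test_frequency_orders_by_n_descending(self):
        ms = self._metrics([("Diarrhoea", 461, 500, 100, 9000), ("Death", 497, 464, 120, 8980)])
        ranked = rank_signals(ms, "frequency")
        assert list(ranked["term"]) == ["Death", "Diarrhoea"]

    def test_strength_orders_by_ebgm05(self):
        ms = self._metrics([("weak", 50, 950, 100, 9000), ("strong", 50, 950, 10, 9090)])
        ranked = rank_signals(ms, "strength")
        assert list(ranked["term"]) == ["strong", "weak"]

    def test_equal_key_breaks_ties_alphabetically(self):
        ms = self._metrics([("zeta", 30, 70, 50, 900), ("alpha", 30, 70, 50, 900)])
        assert list(rank_signals(ms, "frequency")["term"]) == ["alpha", "zeta"]

    def test_empty_list_and_unknown_key(self):
        assert rank_signals([], "frequency").empty
        with pytest.raises(ValueError, match="unknown ranking key"):
            rank_signals([], "size")


def test_evaluate_signal_lists_each_violated_clause():
    m = compute_metrics(table(2, 8, 500, 500))
    ok, failed = evaluate_signal(m)
    assert not ok
    assert "min_n" in failed and "ror_low" in failed
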