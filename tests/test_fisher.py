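"""Contingency-table construction, the exact test and batch classification."""

import math

import numpy as np
import pytest
from scipy import stats

from orfselect.fisher import (
    ContingencyTable,
    adjust_alpha,
    build_table,
    classify_batch,
    fisher_exact,
    round_half_away,
)
from orfselect.genetic_code import SiteCounts
from orfselect.selection import SelectionEstimate, SubstitutionCounts


def _est(d_n, d_s, n_ns_sites, n_s_sites):
    return SelectionEstimate(
        d_n=d_n,
        d_s=d_s,
        sites=SiteCounts(n_s=n_s_sites, n_ns=n_ns_sites),
        subs=SubstitutionCounts(n_s=d_s * n_s_sites, n_ns=d_n * n_ns_sites),
    )


def hypergeom_pvalue_oracle(t: ContingencyTable) -> float:
    """Independent two-sided enumeration via scipy's hypergeometric pmf."""
    r1, r2 = t.row_margins
    c1, _ = t.col_margins
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    xs = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(xs, n, r1, c1)
    p_obs = stats.hypergeom.pmf(t.ns_sub, n, r1, c1)
    return float(min(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(0.4, 0), (0.5, 1), (10.5, 11), (10.49, 10), (2.0, 2)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestBuildTable:
    def test_product_and_round_rule(self):
        t = build_table(_est(d_n=0.1, d_s=0.3, n_ns_sites=600.7, n_s_sites=200.3))
        assert (t.ns_sub, t.ns_unsub, t.s_sub, t.s_unsub) == (60, 541, 60, 140)

    def test_no_substitutions(self):
        t = build_table(_est(d_n=0.0, d_s=0.0, n_ns_sites=300, n_s_sites=100))
        assert (t.ns_sub, t.s_sub) == (0, 0)
        assert t.row_margins == (300, 100)

    def test_half_substitution_rounds_up(self):
        t = build_table(_est(d_n=0.0, d_s=10.5 / 100.0, n_ns_sites=300, n_s_sites=100))
        assert t.s_sub == 11

    def test_clamp_when_cell_exceeds_margin(self, caplog):
        # d_S close to 1 with margins rounding down can overflow the margin
        est = SelectionEstimate(
            d_n=0.0,
            d_s=1.0,
            sites=SiteCounts(n_s=10.4, n_ns=30.0),
            subs=SubstitutionCounts(n_s=10.4, n_ns=0.0),
        )
        with caplog.at_level("WARNING"):
            t = build_table(est)
        assert t.s_sub == t.row_margins[1] == 10
        assert t.s_unsub == 0


class TestFisherExact:
    def test_identical_rows_give_one(self):
        assert fisher_exact(ContingencyTable(5, 95, 5, 95)) == 1.0

    def test_perfect_separation_10v10(self):
        # only x=10 and x=0 are as extreme; 2 / C(20,10)
        p = fisher_exact(ContingencyTable(10, 0, 0, 10))
        assert p == pytest.approx(2 / 184756, rel=1e-12)

    def test_zero_column_margin_gives_one(self):
        assert fisher_exact(ContingencyTable(0, 50, 0, 50)) == 1.0

    def test_zero_row_margin_gives_one(self):
        assert fisher_exact(ContingencyTable(0, 0, 3, 7)) == 1.0

    def test_matches_enumeration_oracle_small_sweep(self):
        """Exhaustive agreement with the hypergeometric oracle, margins <= 12."""
        for r1 in range(13):
            for r2 in range(13):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        t = ContingencyTable(a, r1 - a, c, r2 - c)
                        assert fisher_exact(t) == pytest.approx(
                            hypergeom_pvalue_oracle(t), abs=1e-12
                        ), t

    def test_invariant_under_row_and_column_swaps(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            p = fisher_exact(ContingencyTable(a, b, c, d))
            assert fisher_exact(ContingencyTable(c, d, a, b)) == pytest.approx(p, abs=1e-12)
            assert fisher_exact(ContingencyTable(b, a, d, c)) == pytest.approx(p, abs=1e-12)

    def test_agrees_with_scipy_reference(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, size=4))
            ours = fisher_exact(ContingencyTable(a, b, c, d))
            ref = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


class TestAdjustAlpha:
    @pytest.mark.parametrize(
        "m,alpha,expected",
        [(1, 0.05, 0.05), (1000, 0.05, 0.001), (10, 0.5, 0.1)],
    )
    def test_one_false_positive_policy(self, m, alpha, expected):
        assert adjust_alpha(m, alpha) == pytest.approx(expected)

    def test_bonferroni_and_none_policies(self):
        assert adjust_alpha(20, 0.05, "bonferroni") == pytest.approx(0.0025)
        assert adjust_alpha(20, 0.05, "none") == 0.05

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            adjust_alpha(0, 0.05)

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="policy"):
            adjust_alpha(10, 0.05, "fdr")


class TestClassifyBatch:
    def test_single_nonsignificant_pair_is_dubious(self):
        # 10 of 100 nonsyn vs 8 of 100 syn: clearly compatible rows
        [res] = classify_batch([_est(0.10, 0.08, 100, 100)], alpha_nominal=0.05)
        assert res.p_value > 0.05
        assert res.verdict == "dubious"
        assert res.m_tests == 1

    def test_strong_separation_is_confirmed(self):
        [res] = classify_batch([_est(0.02, 0.50, 600, 200)], alpha_nominal=0.05)
        assert res.p_value <= res.alpha_adjusted
        assert res.verdict == "confirmed"

    def test_threshold_uses_adjusted_alpha(self):
        # one real signal among 100 identical weak items: alpha_adj = 0.01
        weak = _est(0.10, 0.16, 300, 100)
        batch = classify_batch([weak] * 100, alpha_nominal=0.05)
        assert batch[0].alpha_adjusted == pytest.approx(0.01)
        for res in batch:
            expected = "confirmed" if res.p_value <= 0.01 else "dubious"
            assert res.verdict == expected

    def test_no_substitutions_is_insufficient(self):
        [res] = classify_batch([_est(0.0, 0.0, 300, 100)])
        assert res.verdict == "insufficient"
        assert res.p_value == 1.0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            classify_batch([])

    def test_per_item_failure_recorded_not_fatal(self):
        bad = SelectionEstimate(
            d_n=0.1, d_s=0.1, sites=SiteCounts(0.0, 0.0), subs=SubstitutionCounts(0, 0)
        )
        good = _est(0.1, 0.1, 100, 100)
        results = classify_batch([bad, good])
        assert results[0].error is not None
        assert math.isnan(results[0].p_value)
        assert results[1].error is None
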