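"""Direction-of-effect enrichment tables and their tests."""

import math

import numpy as np
import pytest
from scipy import stats

from sexassoc import enrichment, io
from sexassoc.datamodel import DataError, EnrichmentTable

from test_sexdiff import make_result


def fisher_enumeration_oracle(a, b, c, d):
    """Exact-integer hypergeometric enumeration over the first cell."""
    r1, r2, c1 = a + b, c + d, a + c
    weights = {
        x: math.comb(r1, x) * math.comb(r2, c1 - x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    total = sum(weights.values())
    obs = weights[a]
    return sum(w for w in weights.values() if w <= obs) / total


class TestClassify:
    @pytest.mark.parametrize(
        "or_, p, expected",
        [
            (0.6, 0.01, "protective"),
            (1.4, 0.2, "not_significant"),
            (1.0, 1.0, "not_significant"),
            (1.4, 0.01, "risk"),
            (0.6, 0.05, "not_significant"),  # strict threshold
        ],
    )
    def test_directions(self, or_, p, expected):
        r = make_result(beta=np.log(or_), se=0.1)
        r.or_, r.p = or_, p
        assert enrichment.classify_direction(r, alpha=0.05) == expected

    def test_rejects_flagged_fit(self):
        r = make_result(flag="separated")
        with pytest.raises(DataError):
            enrichment.classify_direction(r)


class TestPearsonChi2:
    def test_eye_colour_reference_table(self):
        chi2, p = enrichment.pearson_chi2_2x2([[16, 6], [11, 16]])
        assert chi2 == pytest.approx(5.014, abs=0.001)
        assert p == pytest.approx(0.0251, abs=0.0002)

    def test_pooled_reference_table(self):
        _, p = enrichment.pearson_chi2_2x2([[107, 54], [75, 108]])
        assert p == pytest.approx(2.32e-6, rel=0.005)

    def test_balanced_table_is_null(self):
        chi2, p = enrichment.pearson_chi2_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_shortcut_matches_observed_vs_expected(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 40, size=(2, 2))
        chi2, p = enrichment.pearson_chi2_2x2(t)
        ref = stats.chi2_contingency(t, correction=False)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(DataError):
            enrichment.pearson_chi2_2x2([[0, 0], [3, 4]])


class TestFisherExact:
    def test_balanced_unit_table(self):
        assert enrichment.fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_antidiagonal_table(self):
        assert enrichment.fisher_exact_2x2([[0, 5], [5, 0]]) == pytest.approx(
            0.00794, abs=1e-5
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 11, size=4)
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        assert enrichment.fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
            fisher_enumeration_oracle(a, b, c, d), rel=1e-9
        )


class TestTables:
    def test_eye_fixture_percentages(self):
        t = enrichment.attach_tests(
            EnrichmentTable(trait="eye", prot_f=16, risk_f=6, prot_m=11, risk_m=16)
        )
        assert t.pct_prot_f == pytest.approx(72.72, abs=0.01)
        assert t.pct_prot_m == pytest.approx(40.74, abs=0.01)
        assert t.p_chi2 == pytest.approx(0.025, abs=0.001)

    def test_build_trait_table_from_scans(self):
        res_f = [
            make_result(rsid=f"rs{i}", outcome="skin", beta=b, se=0.1)
            for i, b in enumerate([-0.5, -0.6, 0.02, 0.7])
        ]
        res_m = [
            make_result(rsid=f"rs{i}", outcome="skin", beta=b, se=0.1)
            for i, b in enumerate([0.5, 0.6, -0.01, 0.7])
        ]
        t = enrichment.build_trait_table(res_f, res_m, "skin", alpha=0.05)
        assert (t.prot_f, t.risk_f, t.prot_m, t.risk_m) == (2, 1, 0, 3)

    def test_wrong_trait_rejected(self):
        with pytest.raises(DataError):
            enrichment.build_trait_table([make_result(outcome="eye")], [], "skin")

    def test_empty_inputs_zero_counts_no_tests(self):
        t = enrichment.build_trait_table([], [], "eye")
        assert (t.prot_f + t.risk_f + t.prot_m + t.risk_m) == 0
        assert np.isnan(t.p_chi2) and np.isnan(t.p_fisher)

    def test_degenerate_column_fisher_only(self):
        t = enrichment.attach_tests(
            EnrichmentTable(trait="eye", prot_f=4, risk_f=0, prot_m=4, risk_m=0)
        )
        assert np.isnan(t.p_chi2)
        assert t.p_fisher == pytest.approx(1.0)


class TestPooled:
    def test_reference_pooled_counts_and_margins(self):
        tables = [enrichment.attach_tests(t) for t in io.load_enrichment_reference()]
        pooled = enrichment.pooled_enrichment(tables)
        assert (pooled.prot_f, pooled.prot_m) == (107, 75)
        assert pooled.prot_f + pooled.risk_f == sum(t.prot_f + t.risk_f for t in tables)
        assert pooled.p_chi2 == pytest.approx(2.32e-6, rel=0.005)

    def test_single_table_identity(self):
        t = EnrichmentTable(trait="eye", prot_f=3, risk_f=2, prot_m=1, risk_m=4)
        pooled = enrichment.pooled_enrichment([t])
        assert pooled.counts.tolist() == t.counts.tolist()

    def test_trait_order_commutativity(self):
        tables = io.load_enrichment_reference()
        a = enrichment.pooled_enrichment(tables)
        b = enrichment.pooled_enrichment(list(reversed(tables)))
        assert a.counts.tolist() == b.counts.tolist()
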