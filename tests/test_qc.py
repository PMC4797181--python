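"""Genotype QC: call rate, orientation, exact HWE, MAF by sex."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexassoc import qc
from sexassoc.datamodel import DataError
from sexassoc.simulate import SimulationConfig, generate_study

from conftest import make_matrix, make_samples


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact-integer enumeration over heterozygote counts given allele margins."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    if nA == 0 or nA == 2 * n:
        return 1.0
    weights = {}
    for h in range(nA % 2, min(nA, 2 * n - nA) + 1, 2):
        aa = (nA - h) // 2
        bb = n - aa - h
        weights[h] = math.comb(n, aa) * math.comb(n - aa, h) * 2**h
    total = sum(weights.values())
    obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= obs) / total


class TestCallRateFilter:
    def test_removes_fully_missing_variant(self):
        gm = make_matrix([[0, np.nan], [1, np.nan], [2, np.nan]])
        out, report = qc.call_rate_filter(gm, 0.9)
        assert out.rsids == ["rs1"]
        assert report.removed_rsids == ["rs2"]

    def test_panel_scale_accounting(self):
        """384 variants with 21 fully missing leave 363 at threshold 0.9."""
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(20, 384)).astype(float)
        dosage[:, :21] = np.nan
        gm = make_matrix(dosage)
        out, report = qc.call_rate_filter(gm, 0.9)
        assert out.n_variants == 363
        assert report.n_removed == 21
        assert report.removal_fraction == pytest.approx(21 / 384)

    def test_zero_threshold_is_identity(self):
        gm = make_matrix([[0, np.nan], [1, 2]])
        out, report = qc.call_rate_filter(gm, 0.0)
        assert out.rsids == gm.rsids and report.n_removed == 0

    def test_all_removed_warns(self):
        gm = make_matrix([[np.nan], [np.nan]])
        out, report = qc.call_rate_filter(gm, 0.5)
        assert out.n_variants == 0 and report.warning


class TestOrientation:
    def test_reflects_major_coded_variant(self):
        gm = make_matrix([[2], [2], [1]])  # coded-allele freq 5/6
        out = qc.orient_minor_allele(gm)
        np.testing.assert_array_equal(out.dosage[:, 0], [0.0, 0.0, 1.0])
        assert out.variants[0].minor_allele == gm.variants[0].major_allele

    def test_minor_coded_unchanged_and_tie_kept(self):
        gm = make_matrix([[0, 2], [0, 0], [1, 1]])  # freqs 1/6 and 1/2
        out = qc.orient_minor_allele(gm)
        np.testing.assert_array_equal(out.dosage, gm.dosage)
        assert out.variants[1].minor_allele == gm.variants[1].minor_allele

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([0.0, 1.0, 2.0, float("nan")]), min_size=1, max_size=12))
    def test_idempotent(self, column):
        gm = make_matrix([[v] for v in column])
        once = qc.orient_minor_allele(gm)
        twice = qc.orient_minor_allele(once)
        np.testing.assert_array_equal(
            np.nan_to_num(once.dosage, nan=-1), np.nan_to_num(twice.dosage, nan=-1)
        )
        freq = np.nansum(once.dosage) / (2 * np.isfinite(once.dosage).sum() or 1)
        assert freq <= 0.5 + 1e-12

    def test_hemizygous_male_x_reflection(self):
        """Male X dosages reflect 1 - d, females 2 - d, under hemizygous mode."""
        samples = make_samples(["F", "F", "M", "M"])
        gm = make_matrix([[2], [2], [1], [1]], chroms=["X"])
        out = qc.orient_minor_allele(gm, samples)  # freq (4+2)/(4+2)=1 > 0.5
        np.testing.assert_array_equal(out.dosage[:, 0], [0.0, 0.0, 0.0, 0.0])


class TestHWEExact:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((25, 50, 25), 1.0),  # observed het count is the conditional mode
            ((1, 0, 1), 1 / 3),  # only h in {0, 2}; weights 1 and 2
            ((0, 0, 50), 1.0),  # monomorphic
            ((50, 0, 0), 1.0),
        ],
    )
    def test_reference_values(self, counts, expected):
        assert qc.hwe_exact_test(*counts) == pytest.approx(expected, rel=1e-12)

    def test_rejects_negative_or_empty(self):
        with pytest.raises(DataError):
            qc.hwe_exact_test(-1, 0, 1)
        with pytest.raises(DataError):
            qc.hwe_exact_test(0, 0, 0)

    def test_matches_enumeration_oracle_small_n(self):
        """Exact agreement with integer enumeration for all tables n <= 30."""
        for n in range(1, 31):
            for n_AA in range(n + 1):
                for n_Aa in range(n - n_AA + 1):
                    n_aa = n - n_AA - n_Aa
                    p = qc.hwe_exact_test(n_AA, n_Aa, n_aa)
                    assert p == pytest.approx(
                        hwe_enumeration_oracle(n_AA, n_Aa, n_aa), abs=1e-10
                    ), (n_AA, n_Aa, n_aa)

    def test_symmetric_in_homozygote_labels(self):
        for args in [(3, 5, 10), (0, 2, 7), (4, 4, 4)]:
            assert qc.hwe_exact_test(*args) == pytest.approx(
                qc.hwe_exact_test(args[2], args[1], args[0]), rel=1e-12
            )


class TestHWEScreen:
    def test_bonferroni_threshold_of_the_panel(self):
        """0.05 / 363 = 1.3774e-4 (prints as 1.37e-4 after mantissa truncation)."""
        thr = qc.bonferroni_threshold(0.05, 363)
        assert thr == pytest.approx(1.3774e-4, rel=1e-4)
        mantissa = math.floor(thr * 10**6) / 100  # truncate to 3 digits
        assert mantissa == 1.37  # 1.3774e-4 -> printed 1.37e-4

    def test_threshold_boundary_is_in_hwe(self):
        gm = make_matrix([[2], [0]])  # nAA=1 nAa=0 naa=1 -> p = 1/3
        results, thr = qc.hwe_screen(gm, alpha=1 / 3, m=1)
        assert thr == pytest.approx(1 / 3)
        assert results[0].p_exact == pytest.approx(1 / 3)
        assert results[0].in_hwe  # p == threshold passes (strict inequality flags)

    def test_m_one_threshold_is_alpha(self):
        assert qc.bonferroni_threshold(0.05, 1) == 0.05

    def test_strata_and_x_handling(self):
        samples = make_samples(["F", "F", "M", "M"])
        gm = make_matrix([[0, 1], [1, 1], [2, 1], [1, 0]], chroms=["1", "X"])
        results, _ = qc.hwe_screen(gm, samples)
        by = {(r.rsid, r.stratum) for r in results}
        assert ("rs1", "F") in by and ("rs1", "M") in by and ("rs1", "all") in by
        assert ("rs2", "F") in by and ("rs2", "M") not in by  # X: females only

    def test_bonferroni_conservative_under_null(self):
        """Simulated HWE genotypes rarely flag at alpha/m over 1200 variants."""
        cfg = SimulationConfig(
            seed=99, n_snps=1200, n_x_snps=0, missing_rate=0.0,
            n_female_case=150, n_female_control=150, n_male_case=150, n_male_control=150,
        )
        gm, samples, _ = generate_study(cfg)
        results, thr = qc.hwe_screen(gm, samples, alpha=0.05)
        flagged = sum(not r.in_hwe for r in results)
        assert flagged / len(results) <= 0.05


class TestMafBySex:
    def test_equal_distributions_give_equal_mafs_and_r2_one(self):
        samples = make_samples(["F", "F", "M", "M"])
        gm = make_matrix([[0, 1], [1, 2], [0, 1], [1, 2]])
        summaries, r2 = qc.maf_by_sex(gm, samples)
        for s in summaries:
            assert s.maf_f == pytest.approx(s.maf_m)
        assert r2 == pytest.approx(1.0)

    def test_simulated_panel_concordance(self, study_layout):
        """Both sexes drawn from the same MAFs give R^2 near 1 at study n."""
        gm, samples, _ = study_layout
        gm = qc.orient_minor_allele(gm, samples)
        _, r2 = qc.maf_by_sex(gm, samples)
        assert r2 >= 0.95

    def test_empty_stratum_excluded(self):
        samples = make_samples(["F", "F", "M"])
        gm = make_matrix([[0, 1], [1, 0], [np.nan, 1]])
        summaries, _ = qc.maf_by_sex(gm, samples)
        assert np.isnan(summaries[0].maf_m) and summaries[0].n_m == 0


class TestAlleleCountSexTest:
    def test_identical_counts_p_one(self):
        samples = make_samples(["F", "F", "M", "M"])
        gm = make_matrix([[0], [2], [0], [2]])
        assert qc.allele_count_sex_test(gm, samples, "rs1") == pytest.approx(1.0)

    def test_skewed_counts_significant(self):
        # F: 10 minor / 90 major, M: 50 / 50
        samples = make_samples(["F"] * 50 + ["M"] * 50)
        dosage = [[0]] * 40 + [[1]] * 10 + [[1]] * 50
        gm = make_matrix(dosage)
        p = qc.allele_count_sex_test(gm, samples, "rs1")
        assert p < 0.001

    def test_x_uses_hemizygous_male_alleles(self):
        samples = make_samples(["F", "M", "M"])
        gm = make_matrix([[1], [1], [0]], chroms=["X"])
        # F alleles: 1 minor / 1 major; M alleles: 1 minor / 1 major
        assert qc.allele_count_sex_test(gm, samples, "rs1") == pytest.approx(1.0)

    def test_empty_stratum_errors(self):
        samples = make_samples(["F", "F"])
        gm = make_matrix([[0], [1]])
        with pytest.raises(DataError):
            qc.allele_count_sex_test(gm, samples, "rs1")
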