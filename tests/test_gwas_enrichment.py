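import itertools

import numpy as np
import pytest
from scipy.stats import chi2

from lactnet.core_io import GenomicInterval, SnpRecord
from lactnet.gwas_enrichment import (
    FeatureSet,
    LitterRecord,
    hwe_chisq,
    map_snps_to_features,
    milk_ability_phenotype,
    minor_allele_frequency,
    permutation_enrichment,
    snp_qc,
    sum_statistic,
)


class TestMilkAbility:
    def test_formula(self):
        assert milk_ability_phenotype(LitterRecord(60, 15, 5, 2, 3)) == 45

    def test_all_zero(self):
        assert milk_ability_phenotype(LitterRecord(0, 0, 0, 0, 0)) == 0

    def test_negative_result_permitted(self):
        assert milk_ability_phenotype(LitterRecord(10, 15, 0, 0, 0)) == -5

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            LitterRecord(-1, 0, 0, 0, 0)


def snp(i, pos, beta=0.1, chrom="chr1", geno=None):
    return SnpRecord(f"s{i}", chrom, pos, beta, geno)


class TestSnpQc:
    def test_exact_hwe_kept(self):
        s = snp(1, 10, geno=(25, 50, 25))
        kept, report = snp_qc([s])
        assert kept == [s]
        assert report["maf"][0] == 0.5
        assert report["hwe_chi2"][0] == 0.0
        assert report["hwe_p"][0] == 1.0

    def test_low_maf_removed(self):
        kept, report = snp_qc([snp(1, 10, geno=(99, 1, 0))])
        assert kept == []
        assert report["maf"][0] == pytest.approx(0.005)

    def test_hwe_deviation_removed(self):
        kept, report = snp_qc([snp(1, 10, geno=(50, 0, 50))])
        assert kept == []
        assert report["hwe_chi2"][0] == pytest.approx(100.0)
        assert report["hwe_p"][0] < 0.001

    def test_hwe_chisq_matches_hand_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.multinomial(200, [0.3, 0.5, 0.2])
            n_aa, n_ab, n_bb = (int(c) for c in counts)
            stat, p = hwe_chisq(n_aa, n_ab, n_bb)
            n = n_aa + n_ab + n_bb
            pa = (2 * n_aa + n_ab) / (2 * n)
            exp = [n * pa**2, 2 * n * pa * (1 - pa), n * (1 - pa) ** 2]
            obs = [n_aa, n_ab, n_bb]
            expect = sum((o - e) ** 2 / e for o, e in zip(obs, exp) if e > 0)
            assert stat == pytest.approx(expect)
            assert p == pytest.approx(float(chi2.sf(expect, 1)))

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            minor_allele_frequency(0, 0, 0)

    def test_missing_genotypes_error(self):
        with pytest.raises(ValueError, match="genotype"):
            snp_qc([snp(1, 10)])


class TestMapping:
    fs = FeatureSet("set", (("f1", GenomicInterval("chr1", 20_000, 30_000)),),
                    flank=10_000)

    def test_upstream_within_flank(self):
        assert map_snps_to_features([snp(1, 15_000)], self.fs)

    def test_boundary_exact(self):
        assert map_snps_to_features([snp(1, 10_000)], self.fs)      # start - flank
        assert map_snps_to_features([snp(1, 40_000)], self.fs)      # end + flank
        assert not map_snps_to_features([snp(1, 9_999)], self.fs)
        assert not map_snps_to_features([snp(1, 40_001)], self.fs)

    def test_other_chrom_unassigned(self):
        assert not map_snps_to_features([snp(1, 25_000, chrom="chr9")], self.fs)

    def test_overlapping_features_dedup(self):
        fs = FeatureSet("set", (
            ("a", GenomicInterval("chr1", 100, 1000)),
            ("b", GenomicInterval("chr1", 500, 2000)),
        ), flank=0)
        assigned = map_snps_to_features([snp(1, 700)], fs)
        assert len(assigned) == 1       # m_g counts the SNP once


class TestSumStatistic:
    def test_half(self):
        assert sum_statistic(np.array([0.5, -0.5])) == pytest.approx(0.5)

    def test_zeros(self):
        assert sum_statistic(np.zeros(10)) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            sum_statistic(np.array([]))

    def test_loop_oracle(self):
        rng = np.random.default_rng(1)
        b = rng.normal(size=100)
        assert sum_statistic(b) == pytest.approx(sum(x * x for x in b))


def toy_universe(betas, feature_positions):
    """SNPs at positions 1..n on chr1; feature covering given positions."""
    snps = [snp(i, i + 1, beta=b) for i, b in enumerate(betas)]
    ivs = tuple(
        (f"f{p}", GenomicInterval("chr1", p + 1, p + 1)) for p in feature_positions
    )
    return snps, FeatureSet("toy", ivs, flank=0)


class TestPermutationEnrichment:
    def test_exhaustive_enumeration_c42(self):
        betas = [3.0, 2.0, 0.5, 0.1]
        snps, fs = toy_universe(betas, [0, 1])       # feature holds top-beta^2 pair
        res = permutation_enrichment(snps, fs, n_perm=40_000, seed=0)
        t_obs = 3.0**2 + 2.0**2
        sums = [sum(betas[i] ** 2 for i in pair)
                for pair in itertools.combinations(range(4), 2)]
        exact = sum(s >= t_obs for s in sums) / len(sums)       # = 1/6
        assert res.m_g == 2
        assert res.t_obs == pytest.approx(t_obs)
        # +1 correction vanishes as n_perm grows; compare within MC error
        assert res.p_emp == pytest.approx(exact, abs=0.01)
        assert res.fold == pytest.approx(t_obs / np.mean(sums), rel=0.05)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        snps, fs = toy_universe(rng.normal(size=50), range(10))
        r1 = permutation_enrichment(snps, fs, n_perm=200, seed=7)
        r2 = permutation_enrichment(snps, fs, n_perm=200, seed=7)
        assert r1.p_emp == r2.p_emp and r1.fold == r2.fold
        np.testing.assert_array_equal(r1.null_sums, r2.null_sums)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        betas = rng.normal(size=60)
        snps1, fs = toy_universe(betas, range(15))
        snps2, _ = toy_universe(3.0 * betas, range(15))
        r1 = permutation_enrichment(snps1, fs, n_perm=500, seed=1)
        r2 = permutation_enrichment(snps2, fs, n_perm=500, seed=1)
        assert r2.t_obs == pytest.approx(9.0 * r1.t_obs)
        np.testing.assert_allclose(r2.null_sums, 9.0 * r1.null_sums, rtol=1e-10)
        assert r1.p_emp == r2.p_emp

    def test_p_bounds(self):
        rng = np.random.default_rng(4)
        snps, fs = toy_universe(rng.normal(size=30), range(5))
        res = permutation_enrichment(snps, fs, n_perm=100, seed=0)
        assert 1.0 / 101 <= res.p_emp <= 1.0

    def test_empty_feature_errors(self):
        snps, _ = toy_universe([0.1, 0.2], [0])
        fs = FeatureSet("far", (("x", GenomicInterval("chr5", 1, 10)),), flank=0)
        with pytest.raises(ValueError, match="no assigned"):
            permutation_enrichment(snps, fs)

    def test_p_mode_strict(self):
        betas = [3.0, 2.0, 0.5, 0.1]
        snps, fs = toy_universe(betas, [0, 1])
        res = permutation_enrichment(snps, fs, n_perm=2000, seed=0, p_mode="gt_plain")
        # strict 'greater than': the observed top pair is never exceeded
        assert res.p_emp == 0.0

    def test_inflated_beta_lowers_p(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=100)
        fs_pos = range(20)
        p_vals = []
        for scale in (1.0, 3.0, 9.0):
            b = base.copy()
            b[:20] = b[:20] * scale
            snps, fs = toy_universe(b, fs_pos)
            p_vals.append(permutation_enrichment(snps, fs, n_perm=500, seed=2).p_emp)
        assert p_vals[0] >= p_vals[1] >= p_vals[2]
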