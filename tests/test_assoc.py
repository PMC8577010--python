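import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tce.assoc import (
    bh_fdr,
    bonferroni_threshold,
    classify_cis_trans,
    genotype_pcs,
    gwas_scan,
    linear_assoc,
)
from tce.io_tables import GenotypeMatrix
from tce.preprocess import build_design


def _random_gt(n_snps, samples, seed, maf=0.3):
    rng = np.random.default_rng(seed)
    dos = rng.binomial(2, maf, size=(n_snps, len(samples))).astype(float)
    idx = pd.Index([f"snp{i}" for i in range(n_snps)], name="snp_id")
    snps = pd.DataFrame({"chrom": "1", "pos": np.arange(1, n_snps + 1) * 1000,
                         "ref": "A", "alt": "G"}, index=idx)
    return GenotypeMatrix(pd.DataFrame(dos, index=idx, columns=samples), snps)


class TestGenotypePCs:
    def test_duplicated_samples_get_identical_scores(self):
        gt = _random_gt(50, [f"s{i}" for i in range(20)], seed=1)
        dos = gt.dosages.copy()
        dos["s1"] = dos["s0"]  # duplicate sample
        gt = GenotypeMatrix(dos, gt.snps)
        pcs = genotype_pcs(gt, k=3)
        np.testing.assert_allclose(pcs.scores.loc["s0"], pcs.scores.loc["s1"],
                                   atol=1e-8)

    def test_scores_orthogonal(self):
        gt = _random_gt(50, [f"s{i}" for i in range(20)], seed=2)
        pcs = genotype_pcs(gt, k=4)
        gram = pcs.scores.to_numpy().T @ pcs.scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_matches_independent_svd(self):
        """Scores equal U*S from scipy's SVD of the standardized matrix."""
        gt = _random_gt(50, [f"s{i}" for i in range(20)], seed=3)
        pcs = genotype_pcs(gt, k=4)
        X = gt.dosages.to_numpy().T
        X = (X - X.mean(0)) / X.std(0)
        import scipy.linalg as sla
        U, S, Vt = sla.svd(X, full_matrices=False)
        ref = U[:, :4] * S[:4]
        # signs are a convention; compare up to sign per component
        for j in range(4):
            got = pcs.scores.to_numpy()[:, j]
            assert (np.allclose(got, ref[:, j], atol=1e-8)
                    or np.allclose(got, -ref[:, j], atol=1e-8))

    def test_k_too_large_raises(self):
        gt = _random_gt(10, [f"s{i}" for i in range(8)], seed=4)
        with pytest.raises(ValueError):
            genotype_pcs(gt, k=8)


class TestLinearAssoc:
    def test_noiseless_slope_recovered_exactly(self, tiny_samples):
        samples = tiny_samples
        gt = _random_gt(1, list(samples.sample_ids), seed=5)
        design = build_design(samples)
        y = pd.Series(0.5 * gt.dosages.iloc[0].to_numpy(),
                      index=samples.sample_ids)
        res = linear_assoc(y, gt, design)
        assert res["beta"].iloc[0] == pytest.approx(0.5, abs=1e-10)
        assert res["p"].iloc[0] < 1e-12

    def test_matches_statsmodels_ols(self, tiny_samples):
        """Slope, SE and p equal an independent full-design OLS fit."""
        import statsmodels.api as sm

        samples = tiny_samples
        gt = _random_gt(3, list(samples.sample_ids), seed=6)
        design = build_design(samples)
        rng = np.random.default_rng(10)
        y = pd.Series(rng.normal(size=len(samples.sample_ids)),
                      index=samples.sample_ids)
        res = linear_assoc(y, gt, design)
        X0 = design.matrix.to_numpy()
        for i, snp in enumerate(gt.snp_ids):
            X = np.column_stack([X0, gt.dosages.loc[snp].to_numpy()])
            fit = sm.OLS(y.to_numpy(), X).fit()
            assert res.loc[snp, "beta"] == pytest.approx(fit.params[-1], rel=1e-9)
            assert res.loc[snp, "se"] == pytest.approx(fit.bse[-1], rel=1e-9)
            assert res.loc[snp, "p"] == pytest.approx(fit.pvalues[-1], rel=1e-6)
            # signed model correlation from the t statistic
            t = fit.tvalues[-1]
            df = fit.df_resid
            r = np.sign(t) * np.sqrt(t * t / (t * t + df))
            assert res.loc[snp, "r_assoc"] == pytest.approx(r, rel=1e-9)

    def test_monomorphic_snp_flagged(self, tiny_samples):
        gt = _random_gt(2, list(tiny_samples.sample_ids), seed=7)
        dos = gt.dosages.copy()
        dos.iloc[0] = 1.0  # monomorphic
        gt = GenotypeMatrix(dos, gt.snps)
        design = build_design(tiny_samples)
        res = linear_assoc(tiny_samples.phenotype, gt, design)
        assert bool(res["monomorphic"].iloc[0])
        assert np.isnan(res["p"].iloc[0])
        assert not np.isnan(res["p"].iloc[1])

    def test_p_uniform_under_permuted_phenotype(self, sim_small):
        """GWAS p-values on label-permuted phenotype pass a KS uniformity test."""
        rng = np.random.default_rng(123)
        samples = sim_small.samples
        perm = samples.data.copy()
        perm["phenotype"] = rng.permutation(perm["phenotype"].to_numpy())
        from tce.io_tables import SampleTable
        design = build_design(SampleTable(perm))
        res = linear_assoc(pd.Series(perm["phenotype"], index=perm.index),
                           sim_small.genotypes, design)
        p = res["p"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestCisTrans:
    GENE = pd.Series({"chrom": "5", "start": 2_000_000, "end": 2_010_000})

    def test_inside_gene_body_is_cis(self):
        assert classify_cis_trans("5", 2_005_000, self.GENE) == "cis"

    def test_exactly_window_away_is_cis(self):
        assert classify_cis_trans("5", 3_010_000, self.GENE, window=1_000_000) == "cis"
        assert classify_cis_trans("5", 3_010_001, self.GENE, window=1_000_000) == "trans"

    def test_other_chromosome_is_trans(self):
        assert classify_cis_trans("6", 2_005_000, self.GENE) == "trans"


class TestThresholds:
    def test_genomewide_chip_threshold(self):
        thr = bonferroni_threshold(0.05, 36_045)
        assert f"{thr:.2E}" == "1.39E-06"
        assert thr == pytest.approx(1.3871e-6, rel=1e-3)

    @pytest.mark.parametrize("alpha,n,expected", [(0.05, 1, 0.05),
                                                  (0.05, 50_000, 1e-6)])
    def test_simple_cases(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)


class TestBH:
    def test_hand_step_up_example(self):
        # p=(0.01,0.02,0.03), m=3: min over j>=i of p_(j) m/j -> all 0.03
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_hand_step_up(self, p):
        """BH equals min_{j>=i} p_(j) * m / j computed with explicit loops."""
        got = bh_fdr(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        sorted_p = np.asarray(p)[order]
        for i in range(m):
            expected[order[i]] = min(
                min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
        np.testing.assert_allclose(got, expected, atol=1e-12)


def test_gwas_scan_includes_positions(sim_small):
    from tce.assoc import genotype_pcs
    from tce.preprocess import build_design

    pcs = genotype_pcs(sim_small.genotypes, 5)
    design = build_design(sim_small.samples, extra=pcs.scores)
    res = gwas_scan(sim_small.samples.phenotype, sim_small.genotypes, design)
    assert {"chrom", "pos", "beta", "p", "r_assoc"} <= set(res.columns)
    assert len(res) == len(sim_small.genotypes.snp_ids)
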