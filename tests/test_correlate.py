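import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tce.correlate import (
    UndefinedCorrelationError,
    correlate_all,
    pearson,
    permutation_fdr,
)


def brute_force_permutation_fdr(obs_p, resid_df, pheno_resid, n_perm, seed,
                                floor=1e-5):
    """Definitional permutation-FDR estimator: explicit loops, scipy p-values,
    the same documented permutation stream (one joint shuffle per round)."""
    rng = np.random.default_rng(seed)
    y = pheno_resid.to_numpy(dtype=float)
    yn = (y - y.mean()) / np.linalg.norm(y - y.mean())
    perm_p = []
    for _ in range(n_perm):
        yp = rng.permutation(yn)
        for g in obs_p.index:
            perm_p.append(stats.pearsonr(resid_df.loc[g].to_numpy(), yp).pvalue)
    raw = {}
    for g, t in obs_p.items():
        n_obs = sum(1 for v in obs_p if v <= t)
        mean_null = sum(1 for v in perm_p if v <= t) / n_perm
        raw[g] = mean_null / n_obs
    # step-up monotone in t, then clip
    order = obs_p.sort_values().index
    fdr = {}
    running = None
    for g in reversed(list(order)):
        running = raw[g] if running is None else min(running, raw[g])
        fdr[g] = min(1.0, max(floor, running))
    return pd.Series(fdr).loc[obs_p.index]


class TestPearson:
    def test_perfect_positive(self):
        r, p = pearson([1, 2, 3], [1, 2, 3])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_negative(self):
        r, _ = pearson([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_evaluated_product_moment(self):
        # x=(1,2,3,4), y=(2,1,4,3): cov=1.5, sx=sy=sqrt(5/3) -> r=0.6
        r, p = pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        ref = stats.pearsonr([1, 2, 3, 4], [2, 1, 4, 3])
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x, y = rng.normal(size=(2, 30))
            r, p = pearson(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2])


class TestCorrelateAll:
    def test_gene_equal_to_phenotype(self):
        y = pd.Series([0.1, -0.5, 1.2, 0.4, -0.9],
                      index=[f"s{i}" for i in range(5)])
        resid = pd.DataFrame([y.to_numpy()], index=["g1"], columns=y.index)
        out = correlate_all(resid, y)
        assert out.loc["g1", "r"] == pytest.approx(1.0)

    def test_zero_variance_gene_flagged_not_failed(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        resid = pd.DataFrame([[0, 0, 0, 0], [1, -1, 2, -2.0]],
                             index=["flat", "ok"], columns=y.index)
        out = correlate_all(resid, y)
        assert bool(out.loc["flat", "zero_variance"])
        assert np.isnan(out.loc["flat", "r"])
        assert not np.isnan(out.loc["ok", "r"])

    def test_output_sorted_by_gene_id(self):
        y = pd.Series([1.0, 2.0, 3.0, 0.0], index=list("abcd"))
        resid = pd.DataFrame(np.random.default_rng(1).normal(size=(3, 4)),
                             index=["z", "a", "m"], columns=y.index)
        out = correlate_all(resid, y)
        assert list(out.index) == ["a", "m", "z"]


class TestPermutationFdr:
    def _fixture(self, n_genes=3, n=12, seed=4):
        rng = np.random.default_rng(seed)
        resid = pd.DataFrame(rng.normal(size=(n_genes, n)),
                             index=[f"g{i}" for i in range(n_genes)],
                             columns=[f"s{j}" for j in range(n)])
        pheno = pd.Series(rng.normal(size=n), index=resid.columns)
        obs = correlate_all(resid, pheno)
        return resid, pheno, obs

    def test_matches_brute_force_enumeration(self):
        """3 genes x 2 permutations: estimator equals the definitional loops."""
        resid, pheno, obs = self._fixture()
        fast = permutation_fdr(obs["p"], resid.loc[obs.index], pheno,
                               n_perm=2, seed=99)
        slow = brute_force_permutation_fdr(obs["p"], resid.loc[obs.index],
                                           pheno, n_perm=2, seed=99)
        np.testing.assert_allclose(fast.to_numpy(), slow.to_numpy(), rtol=1e-9)

    def test_matches_brute_force_larger(self):
        resid, pheno, obs = self._fixture(n_genes=6, n=15, seed=8)
        fast = permutation_fdr(obs["p"], resid.loc[obs.index], pheno,
                               n_perm=7, seed=123)
        slow = brute_force_permutation_fdr(obs["p"], resid.loc[obs.index],
                                           pheno, n_perm=7, seed=123)
        np.testing.assert_allclose(fast.to_numpy(), slow.to_numpy(), rtol=1e-9)

    def test_floor_applied_to_extreme_gene(self):
        """A gene more extreme than every permuted p lands on the 1e-5 floor."""
        rng = np.random.default_rng(2)
        n = 40
        y = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        strong = 0.99 * (y - y.mean()) / y.std() + 0.01 * rng.normal(size=n)
        resid = pd.DataFrame(
            np.vstack([strong, rng.normal(size=(4, n))]),
            index=[f"g{i}" for i in range(5)], columns=y.index)
        obs = correlate_all(resid, y)
        fdr = permutation_fdr(obs["p"], resid.loc[obs.index], y,
                              n_perm=200, seed=1)
        assert fdr["g0"] == pytest.approx(1e-5)

    def test_monotone_in_observed_p(self):
        resid, pheno, obs = self._fixture(n_genes=20, n=30, seed=5)
        fdr = permutation_fdr(obs["p"], resid, pheno, n_perm=200, seed=7)
        joined = pd.DataFrame({"p": obs["p"], "fdr": fdr}).sort_values("p")
        assert (np.diff(joined["fdr"].to_numpy()) >= -1e-12).all()

    def test_reproducible_from_seed_and_seed_mandatory(self):
        resid, pheno, obs = self._fixture(n_genes=5, n=20, seed=6)
        a = permutation_fdr(obs["p"], resid, pheno, n_perm=150, seed=42)
        b = permutation_fdr(obs["p"], resid, pheno, n_perm=150, seed=42)
        pd.testing.assert_series_equal(a, b)
        with pytest.raises(ValueError, match="seed"):
            permutation_fdr(obs["p"], resid, pheno, n_perm=150)

    def test_invariant_to_gene_relabeling(self):
        resid, pheno, obs = self._fixture(n_genes=8, n=25, seed=9)
        fdr = permutation_fdr(obs["p"], resid, pheno, n_perm=100, seed=3)
        renamed = resid.rename(index=lambda g: f"x_{g}")
        obs2 = obs.rename(index=lambda g: f"x_{g}")
        fdr2 = permutation_fdr(obs2["p"], renamed, pheno, n_perm=100, seed=3)
        np.testing.assert_allclose(
            fdr.sort_index().to_numpy(), fdr2.sort_index().to_numpy())

    def test_low_n_perm_warns(self):
        resid, pheno, obs = self._fixture()
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_fdr(obs["p"], resid, pheno, n_perm=10, seed=0)
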