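"""GATES / sPCA / SKAT gene-based tests, pruning rules and BH-FDR."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import snps2genes as s2g
from snps2genes import genetests as gt
from snps2genes.assoc import logistic_assoc
from snps2genes.errors import EstimationError

from conftest import make_variants


def simes(p):
    p = np.sort(np.asarray(p))
    m = p.size
    return (m * p / np.arange(1, m + 1)).min()


class TestLd:
    def test_duplicated_column_r_one(self, rng):
        x = rng.binomial(2, 0.3, (100, 1)).astype(float)
        r, kept = gt.ld_r(np.hstack([x, x]))
        assert r[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        x = rng.binomial(2, rng.uniform(0.1, 0.5, 6), (200, 6)).astype(float)
        r, _ = gt.ld_r(x)
        for i in range(6):
            for j in range(6):
                xi, xj = x[:, i], x[:, j]
                brute = np.mean((xi - xi.mean()) * (xj - xj.mean())) / (xi.std() * xj.std())
                assert r[i, j] == pytest.approx(brute, abs=1e-10)

    def test_independent_snps_small_offdiag(self, rng):
        n = 2000
        x = rng.binomial(2, 0.3, (n, 10)).astype(float)
        r, _ = gt.ld_r(x)
        off = np.abs(r[np.triu_indices(10, 1)])
        assert np.median(off) < 3 / np.sqrt(n)

    def test_all_constant_raises(self):
        with pytest.raises(EstimationError):
            gt.ld_r(np.ones((50, 3)))


class TestGates:
    def test_single_snp_identity(self):
        assert gt.gates_p(np.array([0.01]), np.ones((1, 1))) == pytest.approx(0.01)

    def test_independent_snps_reduce_to_simes(self):
        p = np.array([0.01, 0.2, 0.9])
        assert gt.gates_p(p, np.eye(3)) == pytest.approx(0.03, abs=1e-12)

    def test_perfect_ld_pair_counts_once(self):
        p = np.array([0.01, 0.01])
        ld = np.ones((2, 2))
        # rho(1) = 0.9814 -> m_e = 1.0186: effectively a single test
        assert gt.gates_p(p, ld) == pytest.approx(0.01, abs=5e-4)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=10))
    def test_equals_simes_under_identity_ld(self, pvals):
        p = np.asarray(pvals)
        got = gt.gates_p(p, np.eye(p.size))
        assert got == pytest.approx(simes(p), abs=1e-10)

    def test_bounds(self, rng):
        for _ in range(20):
            m = rng.integers(2, 8)
            x = rng.binomial(2, 0.3, (100, m)).astype(float)
            x += rng.normal(0, 1e-6, x.shape)
            r, _ = gt.ld_r(x)
            p = rng.uniform(1e-5, 1, m)
            g = gt.gates_p(p, r)
            assert p.min() / m <= g <= 1.0


class TestPruningAndFilter:
    def test_maf_prune_strict_boundary(self):
        mafs = np.array([0.010, 0.0101, 0.3])
        assert gt.prune_maf(mafs, np.arange(3)).tolist() == [1, 2]

    def test_all_pruned_empty(self):
        assert gt.prune_maf(np.array([0.001]), np.array([0])).size == 0

    def test_loglik_filter_retains_quarter(self, rng):
        x = rng.binomial(2, 0.3, (100, 4)).astype(float)
        y = rng.binomial(1, 0.5, 100)
        assert gt.loglik_filter(x, y).size == 1  # ceil(0.25*4)
        assert gt.loglik_filter(x[:, :1], y).tolist() == [0]

    def test_strong_snp_retained(self, rng):
        n = 400
        x = rng.binomial(2, 0.3, (n, 8)).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.5 + 1.2 * x[:, 5]))), n)
        kept = gt.loglik_filter(x, y)
        assert 5 in kept.tolist()
        # oracle: per-SNP statsmodels log-likelihood ranking agrees
        lls = [logistic_assoc(x[:, j], y) for j in range(8)]
        ll_direct = gt._univariate_logistic_loglik(x, y)
        best = int(np.argmax(ll_direct))
        assert best == 5

    def test_vectorised_loglik_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.binomial(2, 0.4, (150, 5)).astype(float)
        y = rng.binomial(1, 0.4, 150)
        ll = gt._univariate_logistic_loglik(x, y)
        for j in range(5):
            ref = sm.Logit(y, sm.add_constant(x[:, j])).fit(disp=0).llf
            assert ll[j] == pytest.approx(ref, abs=1e-6)


class TestSpca:
    def test_single_snp_reduces_to_univariate(self, rng):
        x = rng.binomial(2, 0.3, (300, 1)).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.4 + 0.5 * x[:, 0]))), 300)
        p, pc1 = gt.spca_p(x, y)
        z = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std()
        ref = logistic_assoc(z, y)
        assert p == pytest.approx(ref.p, abs=1e-9)

    def test_sign_flip_invariance(self, rng):
        x = rng.binomial(2, 0.3, (200, 6)).astype(float)
        y = rng.binomial(1, 0.5, 200)
        p1, pc1 = gt.spca_p(x, y)
        res = gt._fit_logit(y, gt._design(-pc1, None))
        assert p1 == pytest.approx(float(res.pvalues[1]), abs=1e-9)

    def test_constant_gene_missing(self):
        p, _ = gt.spca_p(np.ones((50, 3)), np.r_[np.ones(25), np.zeros(25)].astype(int))
        assert np.isnan(p)


class TestSkat:
    def test_single_snp_equals_score_test(self, rng):
        n = 300
        g = rng.binomial(2, 0.3, n).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.5 + 0.4 * g))), n)
        res = gt.skat_p(g, y)
        mu = y.mean()
        u = g @ (y - mu)
        v = mu * (1 - mu) * np.sum((g - g.mean()) ** 2)
        ref = scipy.stats.chi2.sf(u**2 / v, 1)
        assert res.p == pytest.approx(ref, abs=1e-6)

    def test_toy_instance_matches_permutations(self, rng):
        # fractional (imputed) dosages keep the permutation null continuous
        n, m, n_perm = 40, 3, 20_000
        g = rng.binomial(2, [0.3, 0.2, 0.4], (n, m)).astype(float)
        g = np.clip(g + rng.normal(0, 0.15, g.shape), 0, 2)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.3 + 0.5 * g[:, 0]))), n)
        res = gt.skat_p(g, y)
        assert res.method == "perm3"
        perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
        q = ((perms - y.mean()) @ g) ** 2
        q_obs = ((y - y.mean()) @ g) ** 2
        p_perm = (q.sum(axis=1) >= q_obs.sum()).mean()
        mc_sd = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p - p_perm) < 3 * mc_sd + 2e-3

    def test_duplicated_column_still_calibrated(self, rng):
        n = 60
        g = rng.binomial(2, 0.3, (n, 2)).astype(float)
        g = np.clip(g + rng.normal(0, 0.15, g.shape), 0, 2)
        g = np.hstack([g, g[:, :1]])
        y = rng.binomial(1, 0.5, n)
        res = gt.skat_p(g, y)
        perms = rng.permuted(np.tile(y, (20_000, 1)), axis=1)
        q = (((perms - y.mean()) @ g) ** 2).sum(axis=1)
        q_obs = (((y - y.mean()) @ g) ** 2).sum()
        p_perm = (q >= q_obs).mean()
        mc_sd = np.sqrt(p_perm * (1 - p_perm) / 20_000)
        assert abs(res.p - p_perm) < 3 * mc_sd + 2e-3

    def test_permutation_moments_match_exhaustive_enumeration(self, rng):
        import itertools

        n = 7
        a = rng.binomial(1, 0.5, n).astype(float)
        a -= a.mean()
        g = rng.binomial(2, 0.4, (n, 2)).astype(float)
        gc = g - g.mean(axis=0)
        s = gc @ gc.T
        qs = np.array([a[list(p)] @ s @ a[list(p)]
                       for p in itertools.permutations(range(n))])
        exact = [(qs**k).mean() for k in (1, 2, 3, 4)]
        got = gt._perm_moments_q(s, a)
        assert np.allclose(got, exact, rtol=1e-10)

    def test_covariate_adjustment_changes_null(self, rng):
        n = 500
        sex = rng.integers(0, 2, n).astype(float)
        g = rng.binomial(2, 0.3, (n, 4)).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.5 + 1.0 * sex))), n)
        res_adj = gt.skat_p(g, y, covariates=sex)
        assert 0 < res_adj.p <= 1


class TestFdr:
    def brute_force_bh(self, p):
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            adj[i] = prev
        return np.minimum(adj, 1.0)

    def test_hand_computed_example(self):
        assert np.allclose(gt.fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_equal_and_singleton(self):
        assert np.allclose(gt.fdr_bh([0.2, 0.2, 0.2]), [0.2] * 3)
        assert np.allclose(gt.fdr_bh([0.7]), [0.7])

    def test_matches_brute_force_on_grid(self):
        rng = np.random.default_rng(99)
        for length in range(1, 7):
            for _ in range(40):
                p = np.round(rng.uniform(0, 1, length), 3).clip(1e-6, 1.0)
                assert np.allclose(gt.fdr_bh(p), self.brute_force_bh(p), atol=1e-12)


class TestScanAndSelect:
    def test_scan_structure(self, small_cohort):
        gene_map = {"geneA": list(range(8)), "geneB": list(range(8, 13))}
        df = gt.gene_based_scan(
            small_cohort.dosages, small_cohort.samples["status"].to_numpy(),
            small_cohort.variants, gene_map,
        )
        assert set(df["method"]) == {"gates", "spca", "skat"}
        assert len(df) == 6
        ok = df.dropna(subset=["p_raw"])
        assert (ok["p_fdr"] >= ok["p_raw"] - 1e-12).all()
        assert (ok["n_retained"] <= ok["n_snps"]).all()

    def test_dag_select_union_and_provenance(self):
        assoc_df = pd.DataFrame({"snp": ["s0", "s1", "s2"], "p": [1e-6, 0.5, 0.2]})
        gene_map = {"gA": [0], "gB": [1], "gC": [2]}
        gene_df = pd.DataFrame({
            "gene": ["gA", "gB", "gC"], "method": "skat",
            "p_raw": [0.001, 0.002, 0.9], "p_fdr": [0.01, 0.05, 0.9],
        })
        out = gt.dag_select(assoc_df, gene_map, gene_df)
        assert out["gene"].tolist() == ["gA", "gB"]
        assert out.set_index("gene")["source"].to_dict() == {"gA": "both", "gB": "gene_based"}

    def test_dag_select_empty(self):
        assoc_df = pd.DataFrame({"snp": ["s0"], "p": [0.5]})
        out = gt.dag_select(assoc_df, {"gA": [0]},
                            pd.DataFrame({"gene": [], "method": [], "p_raw": [], "p_fdr": []}))
        assert out.empty
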