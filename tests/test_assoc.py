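"""Single-marker, stratified, haplotype and diplotype association tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import snps2genes as s2g
from snps2genes import assoc
from snps2genes.errors import EstimationError


def _two_by_two(case_exposed, case_n, ctrl_exposed, ctrl_n):
    status = np.r_[np.ones(case_n), np.zeros(ctrl_n)].astype(int)
    dosage = np.r_[np.ones(case_exposed), np.zeros(case_n - case_exposed),
                   np.ones(ctrl_exposed), np.zeros(ctrl_n - ctrl_exposed)]
    return dosage, status


class TestLogistic:
    def test_matches_two_by_two_odds_ratio(self):
        dosage, status = _two_by_two(30, 100, 10, 100)
        r = assoc.logistic_assoc(dosage, status)
        assert r.or_ == pytest.approx(30 * 90 / (70 * 10), abs=1e-6)
        assert r.ci95[0] < r.or_ < r.ci95[1]

    def test_null_p_uniform(self):
        pvals = []
        base = np.random.default_rng(7)
        for _ in range(150):
            dosage = base.binomial(2, 0.3, 400).astype(float)
            status = base.binomial(1, 0.4, 400)
            pvals.append(assoc.logistic_assoc(dosage, status).p)
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_dosage_raises(self):
        with pytest.raises(EstimationError):
            assoc.logistic_assoc(np.ones(50), np.r_[np.ones(25), np.zeros(25)].astype(int))

    def test_single_class_raises(self):
        with pytest.raises(EstimationError):
            assoc.logistic_assoc(np.arange(10, dtype=float), np.ones(10, dtype=int))

    def test_constant_covariate_leaves_beta_unchanged(self, rng):
        dosage = rng.binomial(2, 0.3, 500).astype(float)
        status = rng.binomial(1, 1 / (1 + np.exp(-(-0.4 + 0.3 * dosage))), 500)
        r0 = assoc.logistic_assoc(dosage, status)
        r1 = assoc.logistic_assoc(dosage, status, covariates=np.full(500, 3.7))
        assert r0.beta == pytest.approx(r1.beta, abs=1e-8)

    def test_allele_flip_inverts_or(self, rng):
        dosage = rng.binomial(2, 0.3, 500).astype(float)
        status = rng.binomial(1, 1 / (1 + np.exp(-(-0.4 + 0.3 * dosage))), 500)
        r = assoc.logistic_assoc(dosage, status)
        rf = assoc.logistic_assoc(2.0 - dosage, status)
        assert rf.beta == pytest.approx(-r.beta, abs=1e-6)
        assert rf.or_ == pytest.approx(1.0 / r.or_, rel=1e-6)
        assert rf.ci95[0] == pytest.approx(1.0 / r.ci95[1], rel=1e-6)

    def test_separation_flagged_not_crashed(self):
        dosage = np.r_[np.full(20, 2.0), np.full(20, 0.0), [1.0, 1.0]]
        status = np.r_[np.ones(20), np.zeros(20), [1, 0]].astype(int)
        r = assoc.logistic_assoc(dosage, status)
        assert not r.converged and np.isnan(r.p)


class TestThresholdsAndTiers:
    @pytest.mark.parametrize(
        "alpha,m,expected",
        [(0.05, 2_292_247, 2.18e-8), (0.05, 1, 0.05), (0.01, 10, 1e-3)],
    )
    def test_bonferroni(self, alpha, m, expected):
        assert assoc.bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=5e-3)

    def test_tiers_crafted_list(self):
        res = pd.DataFrame({
            "snp": list("abcdef"),
            "p": [2e-9, 1e-5, 5e-5, 9e-5, 2e-4, 0.3],
        })
        tiers = assoc.select_suggestive(res)
        # tier1: p <= 1e-5 (boundary in); tier2: 1e-8 < p < 1e-4
        assert tiers["tier1"]["snp"].tolist() == ["a", "b"]
        assert tiers["tier2"]["snp"].tolist() == ["b", "c", "d"]

    def test_empty_results(self):
        tiers = assoc.select_suggestive(pd.DataFrame({"snp": [], "p": []}))
        assert tiers["tier1"].empty and tiers["tier2"].empty


class TestStratified:
    def test_equal_strata_interaction_near_one(self, rng):
        dosage = rng.binomial(2, 0.3, 3000).astype(float)
        sex = rng.integers(1, 3, 3000)
        status = rng.binomial(1, 1 / (1 + np.exp(-(-0.5 + 0.35 * dosage))), 3000)
        r = assoc.stratified_interaction(dosage, status, sex)
        assert r.ci95_int[0] < 1.0 < r.ci95_int[1]

    def test_printed_ratio_two_decimals(self):
        # OR(female)/OR(male) for printed strata ORs 2.12 and 1.33
        assert round(2.12 / 1.33, 2) == 1.59

    def test_sex_specific_effect_recovered(self):
        # females OR 2, males OR 1 -> interaction OR estimates 2
        ests = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 4000
            dosage = rng.binomial(2, 0.3, n).astype(float)
            female = rng.integers(0, 2, n)
            logit = -1.2 + np.log(2.0) * dosage * female
            status = rng.binomial(1, 1 / (1 + np.exp(-logit)))
            r = assoc.stratified_interaction(dosage, status, female + 1)
            ests.append(np.log(r.or_int))
            assert r.or_ratio == pytest.approx(r.or_int, rel=0.25)
        mean, sd = np.mean(ests), np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean - np.log(2.0)) < 3 * sd + 0.05

    def test_empty_stratum_interaction_still_reported(self, rng):
        dosage = rng.binomial(2, 0.3, 200).astype(float)
        sex = np.ones(200, dtype=int)  # all male
        status = rng.binomial(1, 0.4, 200)
        r = assoc.stratified_interaction(dosage, status, sex)
        assert r.female is None and r.male is not None


class TestHaplotypes:
    def test_single_snp_haplotype_reduces_to_snp_test(self, small_cohort):
        hap = small_cohort.haplotypes[:, :, [3]]
        status = small_cohort.samples["status"].to_numpy()
        results = assoc.haplotype_assoc(hap, status, min_freq=0.0)
        minor = next(r for r in results if r.haplotype == "1")
        snp = assoc.logistic_assoc(small_cohort.dosages[:, 3], status)
        assert minor.beta == pytest.approx(snp.beta, abs=1e-9)
        assert minor.p == pytest.approx(snp.p, abs=1e-9)

    def test_two_haplotype_system_reciprocal_ors(self):
        cfg = s2g.SimConfig(n_cases=200, n_controls=200,
                            blocks=[s2g.BlockSpec(5, 2, 0.0)],
                            maf_range=(0.4, 0.5), causal_snps=[(0, 1.6)], seed=13)
        cohort = s2g.simulate_cohort(cfg)
        res = assoc.haplotype_assoc(cohort.haplotypes,
                                    cohort.samples["status"].to_numpy())
        assert len(res) == 2
        assert res[0].or_ == pytest.approx(1.0 / res[1].or_, rel=1e-6)
        total = sum(r.freq_all for r in res)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_case_control_frequencies_sum(self, small_cohort):
        res = assoc.haplotype_assoc(small_cohort.haplotypes[:, :, :8],
                                    small_cohort.samples["status"].to_numpy(),
                                    min_freq=0.0)
        assert sum(r.freq_case for r in res) == pytest.approx(1.0, abs=1e-9)
        assert sum(r.freq_control for r in res) == pytest.approx(1.0, abs=1e-9)

    def test_no_haplotype_passes_min_freq_warns(self, small_cohort):
        with pytest.warns(UserWarning):
            out = assoc.haplotype_assoc(small_cohort.haplotypes,
                                        small_cohort.samples["status"].to_numpy(),
                                        min_freq=0.99)
        assert out == []


class TestDiplotypes:
    def test_all_major_is_h1h1(self):
        hap = np.zeros((10, 2, 3), dtype=np.int8)
        status = np.r_[np.ones(5), np.zeros(5)].astype(int)
        classes, _ = assoc.mapt_diplotype(hap, status, r_min=0.0)
        assert set(classes) == {"H1/H1"}

    def test_hardy_weinberg_class_frequencies(self):
        cfg = s2g.SimConfig(n_cases=0, n_controls=2000,
                            blocks=[s2g.BlockSpec(3, 2, 0.0, (0.78, 0.22))],
                            maf_range=(0.22, 0.22), baseline_logit=-30, seed=3)
        # baseline -30 makes everyone a control: a population sample
        cohort = s2g.simulate_cohort(cfg)
        status = np.zeros(2000, dtype=int)
        status[:1000] = 1  # arbitrary labels; only class counts matter here
        classes, table = assoc.mapt_diplotype(cohort.haplotypes, status)
        freq = pd.Series(classes).value_counts(normalize=True)
        h2 = cohort.haplotypes.sum(axis=(1, 2)).sum() / (2 * 3 * 2000)
        expected = {"H1/H1": (1 - h2) ** 2, "H1/H2": 2 * h2 * (1 - h2), "H2/H2": h2**2}
        for k, v in expected.items():
            assert freq.get(k, 0.0) == pytest.approx(v, abs=0.03)

    def test_protective_diplotype_recovered(self):
        ors = []
        for seed in range(6):
            cfg = s2g.SimConfig(
                n_cases=516, n_controls=909,
                blocks=[s2g.BlockSpec(3, 2, 0.0, (0.78, 0.22))], maf_range=(0.22, 0.22),
                causal_diplotype=(0, 1, 0.54), baseline_logit=-2.0, seed=seed,
            )
            cohort = s2g.simulate_cohort(cfg)
            # founder 1 is the minor-allele (H2) haplotype in a 2-founder block
            assert cohort.founders[0][1].sum() == 3
            _, table = assoc.mapt_diplotype(
                cohort.haplotypes, cohort.samples["status"].to_numpy())
            ors.append(np.log(table.set_index("diplotype").loc["H2/H2", "or"]))
        mean, sd = np.mean(ors), np.std(ors, ddof=1) / np.sqrt(len(ors))
        assert np.exp(mean) < 1.0
        assert abs(mean - np.log(0.54)) < 3 * sd + 0.1

    def test_recombinant_haplotypes_warn(self, rng):
        hap = np.zeros((50, 2, 3), dtype=np.int8)
        hap[:10, 0, :] = 1          # clean H2
        hap[11, 0, 0] = 1           # recombinant: single minor allele
        status = rng.binomial(1, 0.5, 50)
        status[0] = 1
        status[1] = 0
        with pytest.warns(UserWarning):
            classes, _ = assoc.mapt_diplotype(hap, status, r_min=0.0)
        assert classes[11] == "H1/H1"  # majority vote keeps the sample
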