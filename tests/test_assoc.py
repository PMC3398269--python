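"""Rare pooling, haplotype logistic regression, weighted TDT, exact CIs
and the two Bonferroni corrections."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from msrhap import phasing, simulate
from msrhap.assoc import (
    RegressionConfig,
    bonferroni_replication,
    bonferroni_search,
    haplotype_lrt,
    mcnemar_exact_ci,
    pool_rare,
    single_haplotype_test,
    tdt_from_counts,
    tdt_global,
    weighted_tdt,
)
from msrhap.phasing import FamilyConfig, em_families

from conftest import fit_logit_oracle, make_families

POOL = {"11": 0.3, "12": 0.2, "21": 0.25, "22": 0.25}


class TestPoolRare:
    def test_threshold_rule(self):
        freqs = {"a": 0.50, "b": 0.30, "c": 0.12, "d": 0.05, "e": 0.03}
        res = pool_rare(freqs)
        assert res.pooled == ["e"]
        assert res.drop_pooled  # pooled mass 0.03 < 0.05
        assert res.baseline == "a"
        assert res.predictors == ["b", "c", "d"]
        assert not res.skip

    def test_single_common_haplotype_leaves_no_predictors(self):
        res = pool_rare({"a": 0.96, "b": 0.04})
        assert res.kept == ["a"] and res.drop_pooled
        assert res.predictors == []
        assert not res.skip  # handled downstream as a no_variation skip

    def test_all_rare_skips(self):
        freqs = {f"h{i}": 0.04 for i in range(25)}
        assert pool_rare(freqs).skip

    def test_low_keep_floor_keeps_rare_haplotypes(self):
        cfg = RegressionConfig(rare_threshold=0.05, min_keep_freq=0.001)
        res = pool_rare({"a": 0.95, "b": 0.045, "c": 0.005}, cfg)
        assert res.kept == ["a", "b", "c"]


class TestHaplotypeLrt:
    def test_constant_column_skipped_as_no_variation(self):
        test = haplotype_lrt(np.ones((20, 1)), np.array([1, 2] * 10))
        assert test.skipped and test.skip_reason == "no_variation"
        assert test.p == 1.0

    def test_complete_separation_skipped(self):
        test = haplotype_lrt(np.array([2.0, 2.0, 0.0, 0.0]), np.array([2, 2, 1, 1]))
        assert test.skipped and test.skip_reason == "separation"

    def test_one_phenotype_class_rejected(self):
        with pytest.raises(ValueError):
            haplotype_lrt(np.arange(4.0), np.array([2, 2, 2, 2]))

    def test_optimizer_oracle_on_integer_counts(self, rng):
        """LRT matches a generic-optimizer logistic fit on phase-certain data."""
        d = rng.integers(0, 3, size=40).astype(float)
        ph = np.where(rng.random(40) < 1 / (1 + np.exp(-(0.5 * d - 0.3))), 2, 1)
        if len(set(ph)) == 1:  # pragma: no cover - guard for the fixed seed
            ph[0] = 1 if ph[0] == 2 else 2
        test = haplotype_lrt(d, ph)
        y = (ph == 2).astype(float)
        X_full = np.column_stack([np.ones(40), d])
        beta_full, ll_full = fit_logit_oracle(X_full, y)
        _, ll_red = fit_logit_oracle(np.ones((40, 1)), y)
        assert test.chi2 == pytest.approx(2 * (ll_full - ll_red), abs=1e-6)
        assert test.loglik_full == pytest.approx(ll_full, abs=1e-6)
        assert test.df == 1

    def test_model_criteria_definitions(self, rng):
        d = rng.integers(0, 3, size=60).astype(float)
        ph = np.array([1, 2] * 30)
        test = haplotype_lrt(d, ph)
        k = 2  # intercept + one dosage column
        assert test.aic == pytest.approx(2 * k - 2 * test.loglik_full)
        assert test.bic == pytest.approx(k * math.log(60) - 2 * test.loglik_full)
        assert 0.0 <= test.nagelkerke_r2 <= 1.0

    def test_covariates_enter_both_models(self, rng):
        n = 200
        d = rng.integers(0, 3, size=n).astype(float)
        cov = rng.normal(size=n)
        logit = -0.2 + 0.8 * cov
        ph = np.where(rng.random(n) < 1 / (1 + np.exp(-logit)), 2, 1)
        plain = haplotype_lrt(d, ph)
        adj = haplotype_lrt(d, ph, covariates=cov)
        # d is independent of phenotype given cov; the LRT df is unchanged
        assert adj.df == plain.df == 1
        assert adj.loglik_reduced > plain.loglik_reduced

    def test_null_p_values_uniform_under_permutation(self, rng):
        """Kolmogorov-Smirnov check of null uniformity over permutations."""
        n = 120
        ds = simulate.sim_case_control(
            simulate.SimConfig(hap_pool=POOL, n_cases=n // 2,
                               n_controls=n // 2, seed=77)
        )
        _, post = phasing.em_unrelated(ds, ["snp1", "snp2"])
        D, cols = phasing.expected_dosages(post, ["11", "12", "21"])
        X = D[:, :3]
        ph = ds.phenotypes
        ps = []
        for _ in range(500):
            perm = rng.permutation(ph)
            t = haplotype_lrt(X, perm)
            if not t.skipped:
                ps.append(t.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSingleHaplotypeTest:
    def test_balanced_design_gives_null_effect(self):
        # dosage distribution identical in both phenotype groups
        d = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        ph = np.array([1, 1, 1, 2, 2, 2])
        eff = single_haplotype_test(d, ph)
        assert eff.beta == pytest.approx(0.0, abs=1e-8)
        assert eff.or_ == pytest.approx(1.0, abs=1e-8)

    def test_optimizer_oracle_and_ci_definition(self, rng):
        d = rng.integers(0, 3, size=20).astype(float)
        ph = np.array([1, 2] * 10)
        eff = single_haplotype_test(d, ph)
        beta, _ = fit_logit_oracle(np.column_stack([np.ones(20), d]), (ph == 2).astype(float))
        assert eff.beta == pytest.approx(beta[1], abs=1e-6)
        assert eff.ci95[0] == pytest.approx(math.exp(eff.beta - 1.96 * eff.se))
        assert eff.ci95[1] == pytest.approx(math.exp(eff.beta + 1.96 * eff.se))
        assert eff.ci95[0] <= eff.or_ <= eff.ci95[1]


def _one_child_config(fid, fpair, mpair, tf, tm, weight=1.0, affected=True):
    return FamilyConfig(
        family_id=fid, father_pair=fpair, mother_pair=mpair,
        transmissions=[(tf, tm)], child_ids=["3"],
        child_affected=[affected], weight=weight,
    )


class TestWeightedTdt:
    @pytest.mark.parametrize(
        "T,U,or2dp",
        [(74.0, 38.0, 1.95), (35.2, 18.3, 1.92), (124.8, 88.6, 1.41),
         (92.0, 54.9, 1.68), (46.8, 68.0, 0.69)],
    )
    def test_odds_ratios_from_weighted_counts(self, T, U, or2dp):
        res = tdt_from_counts(T, U)
        assert round(res.or_, 2) == or2dp

    def test_chi2_from_counts(self):
        assert tdt_from_counts(74.0, 38.0).chi2 == pytest.approx(11.571, abs=5e-4)

    def test_balanced_transmissions_are_null(self):
        res = tdt_from_counts(10.0, 10.0)
        assert res.chi2 == 0.0 and res.p == 1.0 and res.or_ == 1.0

    def test_no_informative_transmissions_flagged(self):
        res = weighted_tdt([], "11")
        assert not res.defined and res.p == 1.0

    def test_hand_count_oracle_on_phased_families(self):
        """Unambiguous families: weighted TDT equals the classical count."""
        hom11 = [(1, 1), (1, 1)]
        hom22 = [(2, 2), (2, 2)]
        het = [(1, 2), (1, 2)]  # parent 11/22 when paired with hom children
        fams = [
            # father het {11,22} transmits 11; mother hom 22
            (het, hom22, [([(1, 2), (1, 2)], 2)]),
            (het, hom22, [([(1, 2), (1, 2)], 2)]),
            # father het transmits 22
            (het, hom22, [(hom22, 2)]),
            (hom11, hom11, [(hom11, 2)]),  # uninformative
        ]
        ds = make_families(fams)
        _, cfgs = em_families(ds, ["snp1", "snp2"])
        res = weighted_tdt(cfgs, "11")
        # hand count: two transmissions of 11, one non-transmission
        assert res.T == pytest.approx(2.0, abs=1e-9)
        assert res.U == pytest.approx(1.0, abs=1e-9)

    def test_affected_only_filter(self):
        cfgs = [
            _one_child_config("F1", ("11", "22"), ("22", "22"), "11", "22"),
            _one_child_config("F2", ("11", "22"), ("22", "22"), "11", "22",
                              affected=False),
        ]
        res = weighted_tdt(cfgs, "11")
        assert res.T == 1.0
        res_all = weighted_tdt(cfgs, "11", affected_only=False)
        assert res_all.T == 2.0

    def test_transmissions_balance_across_haplotypes(self):
        ds = simulate.sim_families(
            simulate.SimConfig(hap_pool=POOL, risk_hap="11", log_or=0.6,
                               n_families=30, seed=13)
        )
        freqs, cfgs = em_families(ds, ["snp1", "snp2"])
        totals = [weighted_tdt(cfgs, h) for h in freqs.freqs]
        sum_t = sum(r.T for r in totals)
        sum_u = sum(r.U for r in totals)
        assert sum_t == pytest.approx(sum_u, abs=1e-9)


class TestTdtGlobal:
    def test_two_haplotype_reduction_to_biallelic(self):
        cfgs = []
        for i in range(6):
            cfgs.append(
                _one_child_config(f"F{i}", ("11", "22"), ("22", "22"),
                                  "11" if i < 4 else "22", "22")
            )
        g = tdt_global(cfgs, ["11", "22"])
        bi = tdt_from_counts(4.0, 2.0)
        assert g.df == 1
        assert g.chi2 == pytest.approx(bi.chi2)

    def test_all_balanced_gives_null(self):
        cfgs = [
            _one_child_config("F1", ("11", "22"), ("22", "22"), "11", "22"),
            _one_child_config("F2", ("11", "22"), ("22", "22"), "22", "22"),
        ]
        g = tdt_global(cfgs, ["11", "22"])
        assert g.chi2 == pytest.approx(0.0)
        assert g.p == pytest.approx(1.0)


class TestMcnemarCI:
    def test_symmetric_counts_cover_one(self):
        lo, hi = mcnemar_exact_ci(10, 10)
        assert lo < 1.0 < hi

    def test_tail_inversion_oracle(self):
        """Endpoints equal the brute-force inversion of the binomial tail."""
        T, U = 74, 38
        n = T + U
        alpha = 0.025

        def upper_tail(p):  # P(X >= T | p)
            return stats.binom.sf(T - 1, n, p)

        def lower_tail(p):  # P(X <= T | p)
            return stats.binom.cdf(T, n, p)

        p_lo = brentq(lambda p: upper_tail(p) - alpha, 1e-12, 1 - 1e-12,
                      xtol=1e-13)
        p_hi = brentq(lambda p: lower_tail(p) - alpha, 1e-12, 1 - 1e-12,
                      xtol=1e-13)
        lo, hi = mcnemar_exact_ci(T, U)
        assert lo == pytest.approx(p_lo / (1 - p_lo), abs=1e-6)
        assert hi == pytest.approx(p_hi / (1 - p_hi), abs=1e-6)
        assert lo <= T / U <= hi

    def test_nesting_with_level(self):
        lo95, hi95 = mcnemar_exact_ci(30, 18, level=0.95)
        lo99, hi99 = mcnemar_exact_ci(30, 18, level=0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_zero_untransmitted_gives_infinite_upper(self):
        lo, hi = mcnemar_exact_ci(5, 0)
        assert math.isinf(hi) and lo > 0


class TestBonferroni:
    def test_search_factor_examples(self):
        assert bonferroni_search(0.5, 94, 4)[1] == 3_188_010
        assert bonferroni_search(0.2, 1, 1) == (0.2, 1)
        assert bonferroni_search(0.001, 5, 3)[1] == 25

    def test_replication_arithmetic_and_cap(self):
        assert bonferroni_replication(0.0001, 300) == pytest.approx(0.03)
        assert bonferroni_replication(0.01, 300) == 1.0
        assert bonferroni_replication(0.42, 1) == 0.42

    def test_monotone_and_capped(self):
        ps = np.linspace(0, 1, 21)
        corr = [bonferroni_search(p, 10, 3)[0] for p in ps]
        assert all(c <= 1.0 for c in corr)
        assert all(a <= b for a, b in zip(corr, corr[1:]))
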