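import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize, stats

from rootmap.genotypes import grm_vanraden, mean_impute
from rootmap.mixedmodel import (
    MixedModelSpec,
    anova_dosage_subpop,
    bic,
    build_design,
    dummy_code,
    fit_null,
    marker_scan,
    reml_loglik_dense,
    select_covariate_model,
)
from rootmap.syndata import TraitPlan, simulate_cohort

from conftest import small_cohort_config


def structured_kinship(n, seed=0):
    r = np.random.default_rng(seed)
    z = r.normal(size=(n, 3))
    k = z @ z.T / 3 + np.eye(n)
    return k / (np.trace(k) / n)


class TestFitNull:
    def test_identity_kinship_pure_noise_no_genetic_variance(self):
        r = np.random.default_rng(0)
        n = 60
        spec = MixedModelSpec(y=r.normal(size=n), x=np.ones((n, 1)),
                              kinship=np.eye(n))
        fit = fit_null(spec)
        # with K = I the two components are non-identified; the genetic
        # share must collapse to the lambda boundary
        assert fit.vc.sigma_g2 / (fit.vc.sigma_g2 + fit.vc.sigma_e2) < 0.01

    def test_restricted_loglik_matches_dense_contrast_density(self):
        r = np.random.default_rng(1)
        n = 5
        k = structured_kinship(n, 1)
        y = r.normal(size=n)
        x = np.column_stack([np.ones(n), r.normal(size=n)])
        spec = MixedModelSpec(y=y, x=x, kinship=k)
        fit = fit_null(spec)
        dense = reml_loglik_dense(y, x, k, fit.vc.sigma_g2, fit.vc.sigma_e2)
        assert fit.vc.reml_loglik == pytest.approx(dense, abs=1e-8)

    def test_heritability_recovery_on_polygenic_traits(self):
        from conftest import planted_cohort_config

        h2 = []
        for seed in range(8):
            cfg = small_cohort_config(
                seed=seed, n_samples=200, subpop_sizes=[50, 50, 50, 50],
                n_snps=800, n_genes=10, n_auto_cis_eqtls=0,
                phenotype_plan={"t": TraitPlan(polygenic_frac=0.5, noise_var=1.0)},
            )
            cohort = simulate_cohort(cfg)
            k = grm_vanraden(mean_impute(cohort.genotypes))
            k = k / (np.trace(k) / 200)
            spec = MixedModelSpec(
                y=cohort.phenotypes["t"].to_numpy(), x=np.ones((200, 1)), kinship=k
            )
            vc = fit_null(spec).vc
            h2.append(vc.sigma_g2 / (vc.sigma_g2 + vc.sigma_e2))
        assert np.mean(h2) == pytest.approx(0.5, abs=0.15)

    def test_non_psd_kinship_rejected(self):
        k = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            fit_null(MixedModelSpec(y=[0.0, 1.0], x=np.ones((2, 1)), kinship=k))


class TestMarkerScan:
    def test_identity_kinship_equals_ols(self):
        r = np.random.default_rng(2)
        n = 50
        y = r.normal(size=n)
        x = np.ones((n, 1))
        m = r.integers(0, 3, size=(n, 30)).astype(float)
        spec = MixedModelSpec(y=y, x=x, kinship=np.eye(n))
        res = marker_scan(spec, m)
        for j in range(m.shape[1]):
            ols = sm.OLS(y, np.column_stack([x, m[:, j]])).fit()
            assert res["p"][j] == pytest.approx(ols.pvalues[-1], abs=1e-8)
            assert res["beta"][j] == pytest.approx(ols.params[-1], abs=1e-8)

    def test_null_calibration_at_five_percent(self):
        r = np.random.default_rng(3)
        n = 120
        k = structured_kinship(n, 3)
        chol = np.linalg.cholesky(k + 1e-9 * np.eye(n))
        y = chol @ r.normal(size=n) + r.normal(size=n)
        m = r.integers(0, 3, size=(n, 5000)).astype(float)  # independent of y
        spec = MixedModelSpec(y=y, x=np.ones((n, 1)), kinship=k)
        res = marker_scan(spec, m)
        frac = (res["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_constant_predictor_yields_missing_row(self):
        r = np.random.default_rng(4)
        n = 30
        m = np.column_stack([np.full(n, 2.0), r.integers(0, 3, size=n)]).astype(float)
        spec = MixedModelSpec(y=r.normal(size=n), x=np.ones((n, 1)),
                              kinship=np.eye(n))
        res = marker_scan(spec, m)
        assert np.isnan(res["p"][0]) and not np.isnan(res["p"][1])

    def test_p3d_false_matches_independent_dense_refit(self):
        r = np.random.default_rng(5)
        n = 40
        k = structured_kinship(n, 5)
        y = np.linalg.cholesky(k + 1e-9 * np.eye(n)) @ r.normal(size=n) \
            + r.normal(size=n)
        m = r.integers(0, 3, size=(n, 10)).astype(float)
        x = np.ones((n, 1))
        spec = MixedModelSpec(y=y, x=x, kinship=k, p3d=False)
        res = marker_scan(spec, m)
        for j in range(10):
            xj = np.column_stack([x, m[:, j]])
            # independent oracle: optimize the dense restricted likelihood
            # over lambda, then dense GLS t-test

            def neg_reml(loglam):
                lam = 10.0 ** loglam
                sg2 = _profile_sg2(y, xj, k, lam)
                return -reml_loglik_dense(y, xj, k, sg2, sg2 * lam)

            opt = optimize.minimize_scalar(neg_reml, bounds=(-5, 5),
                                           method="bounded",
                                           options={"xatol": 1e-8})
            lam = 10.0 ** opt.x
            v = k + lam * np.eye(n)
            vi = np.linalg.inv(v)
            xtvx = xj.T @ vi @ xj
            beta = np.linalg.solve(xtvx, xj.T @ vi @ y)
            resid = y - xj @ beta
            sg2 = float(resid @ vi @ resid) / (n - 2)
            se = np.sqrt(sg2 * np.linalg.inv(xtvx)[-1, -1])
            t = beta[-1] / se
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert res["p"][j] == pytest.approx(p, rel=1e-4, abs=1e-10)

    def test_scan_invariant_under_sample_permutation(self):
        r = np.random.default_rng(6)
        n = 35
        k = structured_kinship(n, 6)
        y = r.normal(size=n)
        m = r.integers(0, 3, size=(n, 12)).astype(float)
        spec = MixedModelSpec(y=y, x=np.ones((n, 1)), kinship=k)
        res = marker_scan(spec, m)
        perm = r.permutation(n)
        spec_p = MixedModelSpec(y=y[perm], x=np.ones((n, 1)),
                                kinship=k[np.ix_(perm, perm)])
        res_p = marker_scan(spec_p, m[perm])
        np.testing.assert_allclose(res["p"], res_p["p"], rtol=1e-6)

    def test_minus_log10_p_monotone_in_abs_t(self):
        r = np.random.default_rng(7)
        n = 45
        spec = MixedModelSpec(y=r.normal(size=n), x=np.ones((n, 1)),
                              kinship=np.eye(n))
        res = marker_scan(spec, r.integers(0, 3, size=(n, 50)).astype(float))
        order = res.dropna().sort_values("minus_log10_p")
        assert order["t"].abs().is_monotonic_increasing


def _profile_sg2(y, x, k, lam):
    n, p = x.shape
    v = k + lam * np.eye(n)
    vi = np.linalg.inv(v)
    beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
    r = y - x @ beta
    return float(r @ vi @ r) / (n - p)


class TestBicSelection:
    def test_identical_specs_identical_bic(self):
        r = np.random.default_rng(8)
        n = 40
        k = structured_kinship(n, 8)
        spec = MixedModelSpec(y=r.normal(size=n), x=np.ones((n, 1)), kinship=k)
        assert bic(spec) == bic(spec)

    def test_irrelevant_covariate_usually_increases_bic(self):
        r = np.random.default_rng(9)
        n = 60
        k = structured_kinship(n, 9)
        wins = 0
        for _ in range(20):
            y = r.normal(size=n)
            plain = MixedModelSpec(y=y, x=np.ones((n, 1)), kinship=k)
            junk = MixedModelSpec(
                y=y, x=np.column_stack([np.ones(n), r.normal(size=n)]), kinship=k
            )
            wins += bic(junk) > bic(plain)
        assert wins >= 18

    def test_recovers_generative_four_group_model(self):
        r = np.random.default_rng(10)
        n = 57
        labels4 = np.repeat(["adm", "aus", "ind", "jap"], [7, 19, 21, 10])
        labels6 = labels4.astype(object).copy()
        labels6[-10:] = np.repeat(["jap_a", "jap_b"], 5)
        k = structured_kinship(n, 10)
        hits = 0
        for _ in range(20):
            means = dummy_code(labels4, drop_first=False) @ r.normal(scale=3, size=4)
            y = means + r.normal(size=n)
            sel = select_covariate_model(y, k, labels4, labels6)
            hits += sel.selected == "subpop4"
        assert hits >= 18

    def test_null_trait_prefers_no_covariates(self):
        r = np.random.default_rng(11)
        n = 57
        labels4 = np.repeat(["a", "b", "c", "d"], [7, 19, 21, 10])
        labels6 = np.repeat(["a", "b", "c", "d", "e", "f"], [7, 19, 21, 4, 3, 3])
        k = np.eye(n)
        hits = 0
        for _ in range(20):
            sel = select_covariate_model(r.normal(size=n), k, labels4, labels6)
            hits += sel.selected == "none"
        assert hits >= 11

    def test_six_group_signal_selects_six_group_model(self):
        r = np.random.default_rng(12)
        n = 60
        labels6 = np.repeat(list("abcdef"), 10)
        labels4 = np.repeat(list("abcd"), 15)
        k = np.eye(n)
        hits = 0
        for _ in range(20):
            means = dummy_code(labels6, drop_first=False) @ r.normal(scale=4, size=6)
            y = means + r.normal(size=n)
            sel = select_covariate_model(y, k, labels4, labels6)
            hits += sel.selected == "subpop6"
        assert hits >= 11

    def test_tie_breaks_toward_fewer_parameters(self):
        # duplicate labelings make models (ii) and (iii) identical designs
        r = np.random.default_rng(13)
        n = 20
        labels = np.repeat(["a", "b"], 10)
        sel = select_covariate_model(r.normal(size=n), np.eye(n), labels, labels)
        assert sel.bics["subpop4"] == pytest.approx(sel.bics["subpop6"])
        if sel.selected != "none":
            assert sel.selected == "subpop4"

    def test_singleton_level_check(self):
        with pytest.raises(ValueError, match="at least one sample"):
            select_covariate_model(
                np.zeros(3), np.eye(3), labels4=np.array(["a", "a", "a"])
            )


class TestAnova:
    def test_null_pvalues_uniform_over_seeds(self):
        r = np.random.default_rng(14)
        n = 57
        labels = np.repeat(["a", "b", "c", "d"], [7, 19, 21, 10])
        pvals = []
        for _ in range(200):
            dosage = r.integers(0, 3, size=n).astype(float)
            expr = r.normal(size=n)
            pvals.append(anova_dosage_subpop(expr, dosage, labels))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_perfect_fit_clamps_at_floor(self):
        n = 57
        r = np.random.default_rng(15)
        dosage = r.integers(0, 3, size=n).astype(float)
        labels = np.repeat(["a", "b", "c", "d"], [7, 19, 21, 10])
        p = anova_dosage_subpop(dosage.copy(), dosage, labels)
        assert p <= 1e-200

    def test_power_on_planted_effect(self):
        r = np.random.default_rng(16)
        n = 57
        labels = np.repeat(["a", "b", "c", "d"], [7, 19, 21, 10])
        hits = 0
        for _ in range(20):
            dosage = r.integers(0, 3, size=n).astype(float)
            expr = 1.0 * dosage + r.normal(scale=0.5, size=n)
            hits += anova_dosage_subpop(expr, dosage, labels) < 0.01
        assert hits >= 18

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            anova_dosage_subpop(np.zeros(10), np.ones(10), ["a"] * 5 + ["b"] * 5)


class TestDesign:
    def test_dummy_coding_drops_alphabetically_first_level(self):
        x = build_design(4, ["b", "a", "c", "a"])
        # columns: intercept, is_b, is_c
        np.testing.assert_array_equal(x[:, 1], [1, 0, 0, 0])
        np.testing.assert_array_equal(x[:, 2], [0, 0, 1, 0])
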