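"""REML fitting: likelihood oracle, recovery, boundary behavior, LRT."""

import numpy as np
import pytest
from scipy import stats

from adigen.coding import allele_freq, code_genotypes
from adigen.greml import compare_decompositions, direct_loglik, fit_greml
from adigen.greml import test_component_zero as lrt_component_zero
from adigen.greml import wald_test_component
from adigen.grm import GRM, build_grms


def random_psd(rng, n, m=None):
    W = rng.standard_normal((n, m or 2 * n))
    M = W @ W.T / (m or 2 * n)
    return M


class TestDirectLoglik:
    def test_identity_covariance_closed_form(self):
        # V = I: restricted logL is the Gaussian log-density of the (n-p)
        # residual contrasts: -0.5*(RSS + (n-p) log 2pi) for orthonormal K
        rng = np.random.default_rng(0)
        n = 12
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        ll = direct_loglik(y, X, [np.eye(n)], [0.5, 0.5])  # V = I
        rss = float(((y - y.mean()) ** 2).sum())
        expected = -0.5 * (rss + (n - 1) * np.log(2 * np.pi))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        n = 30
        G = random_psd(rng, n)
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        c = 2.7
        ll1 = direct_loglik(y, X, [G], [0.8, 0.6])
        ll2 = direct_loglik(np.sqrt(c) * y, X, [G], [c * 0.8, c * 0.6])
        # scaling y by sqrt(c) and all variances by c shifts logL by
        # -(n-p)/2 * log c exactly
        assert ll2 == pytest.approx(ll1 - (n - 2) / 2 * np.log(c), abs=1e-8)

    def test_singular_v_rejected(self):
        n = 8
        with pytest.raises(ValueError, match="singular"):
            direct_loglik(np.zeros(n) + 1.0, None, [np.eye(n)], [0.0, 0.0])


class TestFitGreml:
    def test_matches_direct_loglik_at_fit(self, milk_dataset):
        ds = milk_dataset
        sub = ds.genotypes.subset_samples(ds.phenotypes.ids[:200])
        p = allele_freq(sub)
        sub = sub.subset_variants(np.minimum(p, 1 - p) >= 0.01)
        grms = build_grms(code_genotypes(sub), ("A", "D", "P"))
        y = ds.phenotypes.values.iloc[:200].to_numpy()
        fit = fit_greml(y, None, grms, check_psd=False)
        theta = [fit.sigma2[k] for k in fit.kinds] + [fit.sigma2["e"]]
        oracle = direct_loglik(y, np.ones((200, 1)), grms, theta)
        assert fit.logL == pytest.approx(oracle, abs=1e-6)

    def test_fit_is_optimum_against_random_points(self):
        rng = np.random.default_rng(3)
        n = 40
        G = random_psd(rng, n, 80)
        L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
        y = L @ rng.standard_normal(n) * np.sqrt(1.5) + rng.standard_normal(n)
        X = np.ones((n, 1))
        fit = fit_greml(y, X, [G], check_psd=False)
        vp = np.var(y, ddof=1)
        for _ in range(100):
            theta = rng.uniform(0.01, 2.5, size=2) * vp
            assert fit.logL >= direct_loglik(y, X, [G], theta) - 1e-6

    def test_variance_recovery_additive(self):
        # y ~ N(Xb, 2 G + 1 I): mean estimate over replicates within 10% of 2
        rng = np.random.default_rng(4)
        n = 300
        G = random_psd(rng, n, 400)
        L = np.linalg.cholesky(G + 1e-10 * np.eye(n))
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        b = np.array([1.0, -0.5])
        est = []
        for _ in range(50):
            y = X @ b + np.sqrt(2.0) * (L @ rng.standard_normal(n)) + rng.standard_normal(n)
            fit = fit_greml(y, X, [G], check_psd=False)
            est.append(fit.sigma2["g1"])
        assert abs(np.mean(est) - 2.0) < 0.2

    def test_null_data_hits_zero_boundary(self):
        rng = np.random.default_rng(5)
        n = 200
        G = np.eye(n) * 0 + random_psd(rng, n, 4000)  # near-identity, unrelated
        at_boundary = 0
        for _ in range(10):
            y = rng.standard_normal(n)  # pure noise
            fit = fit_greml(y, None, [G], check_psd=False)
            if fit.sigma2["g1"] < 0.05 * fit.sigma2["e"]:
                at_boundary += 1
        assert at_boundary >= 6

    def test_proportions_sum_to_one_and_se_available(self, milk_dataset):
        ds = milk_dataset
        sub = ds.genotypes.subset_samples(ds.phenotypes.ids)
        p = allele_freq(sub)
        sub = sub.subset_variants(np.minimum(p, 1 - p) >= 0.01)
        grms = build_grms(code_genotypes(sub), ("A", "D", "P"))
        y, X = ds.phenotypes.design()
        fit = fit_greml(y, X, grms, check_psd=False)
        assert fit.converged
        assert sum(fit.proportions.values()) == pytest.approx(1.0, abs=1e-8)
        assert fit.H2 == pytest.approx(
            fit.proportions["A"] + fit.proportions["D"] + fit.proportions["P"]
        )
        assert fit.h2 == fit.proportions["A"]
        assert all(se >= 0 for se in fit.se_sigma2.values())
        assert all(v >= 0 for v in fit.sigma2.values())

    def test_blups_plus_residual_reconstruct_phenotype(self, milk_dataset):
        ds = milk_dataset
        sub = ds.genotypes.subset_samples(ds.phenotypes.ids[:150])
        p = allele_freq(sub)
        sub = sub.subset_variants(np.minimum(p, 1 - p) >= 0.01)
        grms = build_grms(code_genotypes(sub), ("A", "D", "P"))
        y = ds.phenotypes.values.iloc[:150].to_numpy()
        fit = fit_greml(y, None, grms, check_psd=False)
        recon = fit.blups.sum(axis=1).to_numpy() + fit.fixed_effects[0]
        np.testing.assert_allclose(recon, y, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        y = np.arange(10.0)
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_greml(y, X, [np.eye(10)])

    def test_non_psd_grm_rejected(self):
        n = 10
        M = -np.eye(n)
        with pytest.raises(ValueError, match="positive semidefinite"):
            fit_greml(np.random.default_rng(0).standard_normal(n), None, [M])


class TestComponentTest:
    def test_identical_fits_give_half(self):
        rng = np.random.default_rng(6)
        n = 60
        G = random_psd(rng, n)
        y = rng.standard_normal(n)
        full = fit_greml(y, None, [G, random_psd(rng, n)], check_psd=False)
        reduced = fit_greml(y, None, [G], check_psd=False)
        res = lrt_component_zero(full, reduced)
        assert 0 < res["p_value"] <= 0.5
        # equal likelihoods clamp LR to zero: the mixture's point mass gives 1/2
        reduced.logL = full.logL
        assert lrt_component_zero(full, reduced)["p_value"] == 0.5

    def test_boundary_mixture_tail_value(self):
        # LR = 3.84 is the two-sided chi2_1 critical value; the boundary
        # mixture halves its tail: p ~ 0.025
        p = 0.5 * stats.chi2.sf(3.84, 1)
        assert p == pytest.approx(0.025, abs=5e-4)

    def test_mismatched_individuals_rejected(self):
        rng = np.random.default_rng(7)
        G = random_psd(rng, 30)
        ya, yb = rng.standard_normal(30), rng.standard_normal(30)
        fa = fit_greml(ya, None, [GRM(G, "A", 5, [f"a{i}" for i in range(30)])], check_psd=False)
        fb = fit_greml(yb, None, [GRM(G, "A", 5, [f"b{i}" for i in range(30)])], check_psd=False)
        with pytest.raises(ValueError, match="different individuals"):
            lrt_component_zero(fa, fb)

    def test_null_rejection_rate_controlled(self):
        # no dominance simulated: boundary-corrected LRT at alpha = 0.05
        # should reject at most ~7% of the time
        rng = np.random.default_rng(8)
        n = 120
        A = random_psd(rng, n, 240)
        D = random_psd(rng, n, 240)
        LA = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        rejections = 0
        reps = 200
        for _ in range(reps):
            y = LA @ rng.standard_normal(n) + rng.standard_normal(n)
            full = fit_greml(y, None, [A, D], check_psd=False)
            red = fit_greml(y, None, [A], check_psd=False)
            if lrt_component_zero(full, red)["p_value"] < 0.05:
                rejections += 1
        assert rejections / reps <= 0.07

    def test_wald_agrees_in_spirit(self, milk_dataset):
        ds = milk_dataset
        sub = ds.genotypes.subset_samples(ds.phenotypes.ids)
        p = allele_freq(sub)
        sub = sub.subset_variants(np.minimum(p, 1 - p) >= 0.01)
        grms = build_grms(code_genotypes(sub), ("A", "D", "P"))
        y, X = ds.phenotypes.design()
        fit = fit_greml(y, X, grms, check_psd=False)
        res = wald_test_component(fit, "A")
        assert res["p_value"] < 0.01  # strong additive signal


class TestCompareDecompositions:
    def test_zero_nonadditive_signal_reduces_to_additive_fit(self):
        from adigen.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_individuals=400, n_markers=1500, n_qtl=(500, 0, 0),
            target_fractions=(0.4, 0.0, 0.0), seed=99,
        )
        ds = simulate_dataset(cfg)
        sub = ds.genotypes.subset_samples(ds.phenotypes.ids)
        p = allele_freq(sub)
        sub = sub.subset_variants(np.minimum(p, 1 - p) >= 0.01)
        g1 = build_grms(code_genotypes(sub, "genotypic"), ("A", "D", "P"))
        g2 = build_grms(code_genotypes(sub, "noia"), ("A", "Dstar", "P"))
        y, X = ds.phenotypes.design()
        c = compare_decompositions(y, X, g1, g2, check_psd=False)
        # with no dominance or imprinting signal both models collapse onto
        # the additive fit; residual agreement is limited only by the
        # spurious non-additive variance each model picks up
        assert abs(c.H2_diff) < 0.05
        assert c.max_residual_diff < 0.2

    def test_imprinting_proportion_matches_between_models(self, milk_dataset):
        ds = milk_dataset
        sub = ds.genotypes.subset_samples(ds.phenotypes.ids)
        p = allele_freq(sub)
        sub = sub.subset_variants(np.minimum(p, 1 - p) >= 0.01)
        g1 = build_grms(code_genotypes(sub, "genotypic"), ("A", "D", "P"))
        g2 = build_grms(code_genotypes(sub, "noia"), ("A", "Dstar", "P"))
        y, X = ds.phenotypes.design()
        c = compare_decompositions(y, X, g1, g2, check_psd=False)
        # the imprinting matrix is shared, so its variance share agrees
        # far more tightly than the dominance split
        assert abs(c.imprinting_proportion_diff) < 5e-3
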