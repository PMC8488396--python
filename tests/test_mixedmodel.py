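"""REML variance components, the heritability formula and BLUP equations."""

import numpy as np
import pandas as pd
import pytest

from feedgenomics.kinship import build_G
from feedgenomics.mixedmodel import (
    MixedModelREML,
    VarianceComponents,
    heritability,
    predict_ebv,
    reml_fit,
    reml_fit_bivariate,
    solve_mme,
)
from feedgenomics.simpop import SimConfig, simulate_population


class TestHeritabilityFormula:
    @pytest.mark.parametrize(
        "a2,c2,e2,h2,cc2",
        [
            (4.4e-3, 2.4e-3, 2.9e-2, 0.12, 0.07),  # genomic fit, FCR
            (1.41, 0.32, 4.78, 0.22, 0.05),  # genomic fit, BWG
            (7.7e-3, 1.7e-3, 2.8e-2, 0.21, 0.05),  # pedigree fit, FCR
            (2.19, 2.5e-2, 2.02, 0.52, 0.01),  # pedigree fit, FI
        ],
    )
    def test_published_style_variance_rows(self, a2, c2, e2, h2, cc2):
        got_h2, got_c2 = heritability((a2, c2, e2))
        assert round(got_h2, 2) == h2
        assert round(got_c2, 2) == cc2

    def test_no_environment_gives_unit_heritability(self):
        assert heritability((3.0, 0.0, 0.0)) == (1.0, 0.0)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError):
            heritability((0.0, 0.0, 0.0))


class TestRemlAgainstClosedForms:
    def test_balanced_one_way_anova(self, rng):
        # records grouped via the kinship index with K = I reduces the
        # animal model to one-way random effects with closed-form REML
        q, k = 25, 8
        sigma_g2, sigma_e2 = 2.0, 1.0
        g = rng.normal(0, np.sqrt(sigma_g2), q)
        y = np.repeat(g, k) + rng.normal(0, np.sqrt(sigma_e2), q * k)
        X = np.ones((q * k, 1))
        ids = [f"g{i}" for i in range(q)]
        est = MixedModelREML(include_common_env=False).fit(
            X, y, kinship=np.eye(q), record_ids=[i // k for i in range(q * k)]
        )
        means = y.reshape(q, k).mean(axis=1)
        msb = k * np.var(means, ddof=1)
        msw = np.mean(np.var(y.reshape(q, k), axis=1, ddof=1))
        assert est.sigma_e2_ == pytest.approx(msw, rel=1e-4)
        assert est.sigma_a2_ == pytest.approx((msb - msw) / k, rel=1e-3)

    def test_identity_kinship_ebv_is_shrunken_deviation(self, rng):
        n = 40
        y = rng.normal(5.0, 2.0, n)
        X = np.ones((n, 1))
        vc = VarianceComponents(1.0, None, 3.0, 0.25, None)
        _, a_hat, _ = solve_mme(
            y, X, np.eye(n), np.eye(n), np.arange(n), None, 1.0, None, 3.0
        )
        shrink = 1.0 / (1.0 + 3.0 / 1.0)
        expected = shrink * (y - y.mean())
        assert np.allclose(a_hat, expected, atol=1e-6)

    def test_mme_matches_dense_gls_oracle(self, rng):
        n = 8
        L = rng.normal(size=(n, n))
        K = L @ L.T / n + np.eye(n)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)]).astype(float)
        sa2, se2 = 1.3, 0.7
        V = sa2 * K + se2 * np.eye(n)
        Vinv = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        a_oracle = sa2 * K @ Vinv @ (y - X @ beta)
        b_mme, a_mme, _ = solve_mme(
            y, X, K, np.linalg.inv(K), np.arange(n), None, sa2, None, se2
        )
        assert np.allclose(b_mme, beta, atol=1e-8)
        assert np.allclose(a_mme, a_oracle, atol=1e-8)

    def test_ebv_shrink_to_zero_without_genetic_variance(self, rng):
        n = 30
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        _, a_hat, _ = solve_mme(
            y, X, np.eye(n), np.eye(n), np.arange(n), None, 1e-10, None, 1.0
        )
        assert np.abs(a_hat).max() < 1e-6


class TestRemlOnSimulations:
    def test_null_genetic_signal_hits_boundary(self):
        cfg = SimConfig(
            n_families=10, n_snps=600, traits=("T1",), true_h2=(0.0,), true_c2=(0.0,),
            genetic_corr=((1.0,),), trait_means=(0.0,), trait_sds=(1.0,), seed=31,
        )
        _, geno, pheno, _ = simulate_population(cfg)
        vc, _ = reml_fit(pheno, "T1", build_G(geno))
        assert vc.sigma_a2 < 0.01 * pheno["T1"].var()

    def test_recovery_within_two_se(self, signal_population):
        _, _, geno, pheno, _ = signal_population
        vc, _ = reml_fit(pheno, "T1", build_G(geno))
        assert vc.converged
        assert abs(vc.h2 - 0.3) < 2 * vc.se_h2
        assert abs(vc.c2 - 0.05) < 2 * vc.se_c2

    def test_loglik_non_decreasing(self, signal_population):
        _, _, geno, pheno, _ = signal_population
        _, est = reml_fit(pheno, "T1", build_G(geno))
        path = np.asarray(est.loglik_path_)
        assert (np.diff(path) > -1e-6).all()

    def test_swapping_kinship_changes_no_code_path(self, signal_population):
        _, ped, geno, pheno, _ = signal_population
        from feedgenomics.kinship import build_A

        for K in (build_A(ped), build_G(geno)):
            vc, est = reml_fit(pheno, "T1", K)
            assert np.isfinite(vc.h2) and vc.converged

    def test_ebv_truth_correlation_increases_with_h2(self):
        cors = []
        for h2 in (0.1, 0.3, 0.5):
            cfg = SimConfig(
                n_families=10, n_snps=800, traits=("T1",), true_h2=(h2,),
                true_c2=(0.02,), genetic_corr=((1.0,),), trait_means=(0.0,),
                trait_sds=(1.0,), seed=77,
            )
            _, geno, pheno, truth = simulate_population(cfg)
            vc, est = reml_fit(pheno, "T1", build_G(geno))
            bv = truth.breeding_values.loc[pheno["animal"], "T1"]
            cors.append(np.corrcoef(est.ebv_.loc[pheno["animal"]], bv)[0, 1])
        assert cors[0] < cors[1] < cors[2]
        assert cors[0] > 0


class TestBivariate:
    def test_duplicated_trait_has_unit_genetic_correlation(self, signal_population):
        _, _, geno, pheno, _ = signal_population
        pheno = pheno.iloc[:240].copy()
        pheno["T1b"] = pheno["T1"]
        G = build_G(geno)
        vc = reml_fit_bivariate(pheno, "T1", "T1b", G)
        assert vc.rg == pytest.approx(1.0, abs=0.02)

    def test_zero_correlation_recovered(self):
        cfg = SimConfig(
            n_families=12, n_snps=1200, traits=("T1", "T2"),
            true_h2=(0.3, 0.3), true_c2=(0.03, 0.03),
            genetic_corr=((1.0, 0.0), (0.0, 1.0)),
            trait_means=(0.0, 0.0), trait_sds=(1.0, 1.0), seed=41,
        )
        _, geno, pheno, _ = simulate_population(cfg)
        vc = reml_fit_bivariate(pheno, "T1", "T2", build_G(geno))
        assert abs(vc.rg) < 2 * vc.se_rg


class TestPredictEbv:
    def test_masked_animals_still_get_ebv(self, signal_population):
        _, _, geno, pheno, _ = signal_population
        G = build_G(geno)
        vc, _ = reml_fit(pheno, "T1", G)
        masked = pheno["animal"].iloc[:50].tolist()
        ebv = predict_ebv(pheno, "T1", G, vc, mask_animals=masked)
        assert set(masked) <= set(ebv.index)
        assert np.isfinite(ebv.loc[masked]).all()
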