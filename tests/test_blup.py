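"""Mixed-model solves, REML and back-solving against dense oracles."""

import math

import numpy as np
import pytest

from asescale import (
    SNPBLUP,
    PhenotypeSet,
    VarianceComponents,
    backsolve_ase,
    build_grm,
    code_genotypes,
    fit_greml,
    reml_loglik,
    solve_snp_blup,
)
from asescale.simulate import (
    SimulationConfig,
    sample_genotypes,
    simulate_dataset,
    simulate_true_effects,
)
from asescale.coding import apply_variant_filters


def dense_mme_solve(M, pheno, varcomp):
    """Brute-force oracle: full (N+1) x (N+1) mixed-model equations."""
    Z = M.values
    n, N = Z.shape
    wt = pheno.weights
    lam = varcomp.ridge_lambda(M.s_gamma)
    X = np.column_stack([np.ones(n), Z])
    lhs = X.T @ (X * wt[:, None])
    lhs[1:, 1:] += lam * np.eye(N)
    rhs = X.T @ (wt * pheno.y)
    sol = np.linalg.solve(lhs, rhs)
    return sol[0], sol[1:]


def dense_reml_loglik(G, pheno, varcomp):
    """Brute-force oracle: determinant-based restricted log-likelihood."""
    n = pheno.n
    y, wt = pheno.y, pheno.weights
    V = varcomp.sigma_a2 * G + np.diag(varcomp.sigma_e2 / wt)
    Vi = np.linalg.inv(V)
    x = np.ones(n)
    xvx = float(x @ Vi @ x)
    P = Vi - np.outer(Vi @ x, x @ Vi) / xvx
    return -0.5 * (
        (n - 1) * math.log(2 * math.pi)
        + np.linalg.slogdet(V)[1]
        + math.log(xvx)
        + float(y @ P @ y)
    )


class TestSolveSnpBlup:
    def test_infinite_shrinkage_limit(self, ushaped_dataset):
        data, X = ushaped_dataset
        M = code_genotypes(X, gamma=0.0)
        # lambda -> infinity through a vanishing marker variance
        vc = VarianceComponents(1e-12, 1.0)
        fit = solve_snp_blup(M, data.phenotypes, vc)
        wt = data.phenotypes.weights
        weighted_mean = np.sum(wt * data.phenotypes.y) / wt.sum()
        assert np.abs(fit.b_hat).max() < 1e-8
        assert fit.mu_hat == pytest.approx(weighted_mean, abs=1e-8)

    def test_single_locus_scalar_formula(self):
        # a centered column is orthogonal to the intercept under equal
        # weights, so the ridge solution reduces to z'y / (z'z + lambda)
        X = sample_genotypes(np.array([0.4]), 200, seed=3)
        rng = np.random.default_rng(4)
        y = rng.normal(size=200)
        pheno = PhenotypeSet(y=y)
        M = code_genotypes(X, gamma=0.0)
        vc = VarianceComponents(0.5, 1.0)
        fit = solve_snp_blup(M, pheno, vc)
        z = M.values[:, 0]
        lam = vc.ridge_lambda(M.s_gamma)
        expected = (z @ (y - y.mean())) / (z @ z + lam)
        assert fit.b_hat[0] == pytest.approx(expected, rel=1e-8)

    def test_matches_dense_mme_oracle(self):
        X = sample_genotypes(np.array([0.2, 0.4, 0.5]), 5, seed=8)
        rng = np.random.default_rng(9)
        pheno = PhenotypeSet(y=rng.normal(size=5), weights=rng.integers(1, 5, 5))
        M = code_genotypes(X, gamma=-0.5)
        vc = VarianceComponents(M.s_gamma, 1.0)  # lambda = 1
        assert vc.ridge_lambda(M.s_gamma) == pytest.approx(1.0)
        fit = solve_snp_blup(M, pheno, vc)
        mu, b = dense_mme_solve(M, pheno, vc)
        assert fit.mu_hat == pytest.approx(mu, rel=1e-10)
        assert np.allclose(fit.b_hat, b, atol=1e-10)

    @pytest.mark.parametrize("gamma", [0.0, -0.5, -1.0])
    def test_marker_and_individual_level_routes_agree(self, ushaped_dataset, gamma):
        # N > n, so the solver takes the n x n individual-level route; the
        # dense marker-level equations are the independent oracle
        data, X = ushaped_dataset
        M = code_genotypes(X, gamma=gamma)
        vc = VarianceComponents(1.0, 1.0)
        fit = solve_snp_blup(M, data.phenotypes, vc)
        mu, b = dense_mme_solve(M, data.phenotypes, vc)
        assert np.abs(fit.dgv - M.values @ b).max() < 1e-8
        assert fit.mu_hat == pytest.approx(mu, abs=1e-8)

    def test_shrinkage_monotone_in_lambda(self):
        X = sample_genotypes(np.array([0.3]), 100, seed=10)
        rng = np.random.default_rng(11)
        pheno = PhenotypeSet(y=rng.normal(size=100))
        M = code_genotypes(X, gamma=0.0)
        mags = []
        for lam in (0.1, 1.0, 10.0, 100.0, 1000.0):
            vc = VarianceComponents(M.s_gamma / lam, 1.0)
            mags.append(abs(solve_snp_blup(M, pheno, vc).b_hat[0]))
        assert mags == sorted(mags, reverse=True)


class TestBacksolve:
    @pytest.mark.parametrize("gamma", [0.0, -0.5, -1.0])
    def test_equals_direct_estimate(self, ushaped_dataset, gamma):
        data, X = ushaped_dataset
        M = code_genotypes(X, gamma=gamma)
        vc = VarianceComponents(1.0, 1.0)
        fit = solve_snp_blup(M, data.phenotypes, vc)
        G = build_grm(M)
        ase = backsolve_ase(M, G, fit.dgv, vc)
        assert np.abs(ase - fit.ase).max() < 1e-6

    def test_zero_dgv_gives_zero_ase(self, ushaped_dataset):
        _, X = ushaped_dataset
        M = code_genotypes(X, gamma=-1.0)
        G = build_grm(M)
        assert np.allclose(backsolve_ase(M, G, np.zeros(X.n_individuals)), 0.0)

    def test_mismatched_grm_rejected(self, ushaped_dataset):
        _, X = ushaped_dataset
        M = code_genotypes(X, gamma=-1.0)
        G_other = build_grm(code_genotypes(X, gamma=0.0))
        with pytest.raises(ValueError, match="does not match"):
            backsolve_ase(M, G_other, np.zeros(X.n_individuals))


class TestGreml:
    def test_null_data_gives_near_zero_h2(self):
        X = sample_genotypes(np.linspace(0.1, 0.5, 300), 400, seed=12)
        rng = np.random.default_rng(13)
        pheno = PhenotypeSet(y=rng.normal(size=400))
        G = build_grm(code_genotypes(X, gamma=0.0))
        vc, _ = fit_greml(G, pheno)
        assert vc.h2 < 0.1

    def test_reml_optimum_beats_grid(self, uniform_dataset):
        data, X = uniform_dataset
        G = build_grm(code_genotypes(X, gamma=0.0))
        vc, best = fit_greml(G, data.phenotypes)
        total = vc.sigma_a2 + vc.sigma_e2
        for h2 in (0.05, 0.25, 0.45, 0.65, 0.85):
            other = VarianceComponents(h2 * total, (1 - h2) * total)
            assert reml_loglik(G, data.phenotypes, other) <= best + 1e-6

    def test_asymmetric_matrix_rejected(self, uniform_dataset):
        data, _ = uniform_dataset
        bad = np.eye(data.phenotypes.n)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            fit_greml(bad, data.phenotypes)


class TestRemlLoglik:
    def _fixture(self):
        cfg = SimulationConfig(
            n_individuals=30, n_snps=80, h2=0.4, seed=11,
            mean_weight=5.0, weight_model="poisson-like",
        )
        d = simulate_dataset(cfg)
        X, _ = apply_variant_filters(
            d.genotypes, min_minor_copies=1, require_all_genotypes=False
        )
        G = build_grm(code_genotypes(X, gamma=-0.5))
        return G, d.phenotypes

    def test_matches_dense_determinant_oracle(self):
        G, pheno = self._fixture()
        vc = VarianceComponents(0.7, 1.3)
        fast = reml_loglik(G, pheno, vc)
        assert abs(fast - dense_reml_loglik(G, pheno, vc)) < 1e-6

    def test_translation_invariance(self):
        G, pheno = self._fixture()
        vc = VarianceComponents(0.7, 1.3)
        shifted = PhenotypeSet(y=pheno.y + 11.0, weights=pheno.weights)
        assert reml_loglik(G, shifted, vc) == pytest.approx(
            reml_loglik(G, pheno, vc), abs=1e-8
        )

    def test_scale_equivariance(self):
        G, pheno = self._fixture()
        vc = VarianceComponents(0.7, 1.3)
        k = 3.0
        scaled = PhenotypeSet(y=k * pheno.y, weights=pheno.weights)
        vck = VarianceComponents(vc.sigma_a2 * k**2, vc.sigma_e2 * k**2)
        expected = reml_loglik(G, pheno, vc) - (pheno.n - 1) * math.log(k)
        assert reml_loglik(G, scaled, vck) == pytest.approx(expected, abs=1e-8)


class TestCodingContrast:
    def test_dgv_robust_but_rare_ase_inflated_by_scaling(self, ushaped_dataset):
        # scaled coding shrinks rare-variant effects less: genomic values
        # barely move while low-MAF ASE grow in magnitude
        data, X = ushaped_dataset
        vc = VarianceComponents(1.0, 1.0)
        fit_c = solve_snp_blup(code_genotypes(X, 0.0), data.phenotypes, vc)
        fit_cs = solve_snp_blup(code_genotypes(X, -1.0), data.phenotypes, vc)
        dgv_corr = np.corrcoef(fit_c.dgv, fit_cs.dgv)[0, 1]
        ase_corr = np.corrcoef(fit_c.ase, fit_cs.ase)[0, 1]
        assert dgv_corr > 0.95
        assert ase_corr < dgv_corr
        rare = X.maf < 0.05
        assert rare.sum() >= 10
        ratio = np.abs(fit_cs.ase[rare]) / np.abs(fit_c.ase[rare])
        assert np.median(ratio) > 1.0


class TestSNPBLUPEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = SNPBLUP(gamma=-0.5, h2=0.3)
        params = est.get_params()
        assert params["gamma"] == -0.5
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(gamma=0.0)
        assert est.gamma == 0.0

    def test_fit_predict_round_trip(self, uniform_dataset):
        data, X = uniform_dataset
        est = SNPBLUP(gamma=-1.0).fit(
            X, data.phenotypes.y, sample_weight=data.phenotypes.weights
        )
        assert est.coef_.shape == (X.n_snps,)
        # training predictions are mu + DGV
        assert np.allclose(est.predict(X), est.intercept_ + est.dgv_, atol=1e-8)

    def test_fixed_components_skip_reml(self, uniform_dataset):
        data, X = uniform_dataset
        est = SNPBLUP(gamma=0.0, sigma_a2=1.0, sigma_e2=1.0).fit(X, data.phenotypes.y)
        assert est.varcomp_.sigma_a2 == 1.0
        assert est.varcomp_.sigma_e2 == 1.0

    def test_predict_requires_fit(self, uniform_dataset):
        from sklearn.exceptions import NotFittedError

        _, X = uniform_dataset
        with pytest.raises(NotFittedError):
            SNPBLUP().predict(X)

    def test_recovers_simulated_heritability(self):
        # unit weights: with hundreds of effective records per individual the
        # unit-weight residual variance (and hence h2) is barely identified
        cfg = SimulationConfig(
            n_individuals=500, n_snps=800, h2=0.5, mean_weight=1.0, seed=31
        )
        d = simulate_dataset(cfg)
        X, _ = apply_variant_filters(
            d.genotypes, min_minor_copies=2, require_all_genotypes=False
        )
        est = SNPBLUP(gamma=0.0).fit(
            X, d.phenotypes.y, sample_weight=d.phenotypes.weights
        )
        assert est.varcomp_.h2 == pytest.approx(0.5, abs=0.15)
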