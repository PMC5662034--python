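"""Closed-form shrinkage-ratio theory against brute-force grid summations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asescale import (
    FrequencyModel,
    Scenario,
    crossing_maf,
    cstar,
    cstar_exact,
    expected_heterozygosity,
    ratio_curve,
    ratio_general,
    ratio_uniform,
    ratio_ushaped,
)

USHAPED = FrequencyModel("ushaped", ne=65, mutation_rate=1e-8)


def brute_force_heterozygosity(model: FrequencyModel, n: int) -> float:
    """Independent oracle: direct grid sum of 2p(1-p) * phi(p)."""
    p = np.arange(1, 2 * n) / (2 * n)
    if model.kind == "uniform":
        w = np.ones_like(p)
    else:
        w = p ** (model.theta - 1) * (1 - p) ** (model.theta - 1)
    w = w / w.sum()
    return float(np.sum(2 * p * (1 - p) * w))


class TestFrequencyModel:
    def test_density_sums_to_one(self):
        for model in (FrequencyModel("uniform"), USHAPED):
            for n in (10, 500):
                assert abs(model.density(n).sum() - 1.0) < 1e-9
                assert (model.density(n) >= 0).all()

    def test_selection_is_out_of_scope(self):
        with pytest.raises(ValueError):
            FrequencyModel("ushaped", selection_coefficient=0.1)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            FrequencyModel("triangular")


class TestCstar:
    def test_matches_harmonic_sum_oracle(self):
        # exact constant is 1/(4n H_{2n-1}); the closed form approximates it
        for n in (50, 200, 1000, 10_000, 100_000, 1_000_000):
            harmonic = np.sum(1.0 / np.arange(1, 2 * n))
            exact = 1.0 / (4 * n * harmonic)
            assert cstar(n) == pytest.approx(exact, rel=1e-4)
            assert cstar_exact(n) == pytest.approx(exact, rel=1e-12)

    def test_value_at_n_1000(self):
        # frozen from the harmonic-sum oracle: 1/(4000 * H_1999)
        assert cstar(1000) == pytest.approx(3.0570314e-05, rel=1e-4)

    def test_small_theta_regime(self):
        # Ne=65, v=1e-8 gives 4*Ne*v = 2.6e-6, the regime where the
        # closed-form normaliser applies
        assert USHAPED.theta == pytest.approx(2.6e-6)


class TestExpectedHeterozygosity:
    def test_uniform_is_one_third(self):
        assert expected_heterozygosity(FrequencyModel("uniform"), 1000) == 1 / 3

    def test_ushaped_against_grid_sum(self):
        # brute-force summation with the exact normaliser as oracle
        got = expected_heterozygosity(USHAPED, 1000)
        assert got == pytest.approx(0.1222, abs=2e-4)
        assert got == pytest.approx(brute_force_heterozygosity(USHAPED, 1000), rel=1e-3)

    @pytest.mark.parametrize("n", [100, 10_000, 1_000_000])
    def test_approximation_close_to_exact_sum(self, n):
        approx = 2 * cstar(n) * (2 * n - 1)
        exact = brute_force_heterozygosity(USHAPED, n)
        assert abs(approx - exact) / exact < 1e-3

    def test_large_theta_falls_back_to_exact_sum(self):
        hot = FrequencyModel("ushaped", ne=10**6, mutation_rate=1e-6)
        with pytest.warns(UserWarning, match="not negligible"):
            got = expected_heterozygosity(hot, 200)
        assert got == pytest.approx(brute_force_heterozygosity(hot, 200), rel=1e-9)


class TestRatioGeneral:
    def test_ratio_is_one_at_mean_heterozygosity(self):
        # 2p(1-p) = S/N makes numerator and denominator equal
        n_snps, sum_2pq = 1000, 300.0
        p = 0.5 * (1 - math.sqrt(1 - 2 * sum_2pq / n_snps))
        assert ratio_general(0.3, 500, n_snps, p, sum_2pq) == pytest.approx(1.0)

    def test_infinite_data_limit(self):
        assert ratio_general(0.5, 10**12, 1000, 0.01, 333.0) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_boundary_h2_rejected(self):
        for h2 in (0.0, 1.0):
            with pytest.raises(ValueError):
                ratio_general(h2, 100, 100, 0.3, 30.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        p=st.floats(0.001, 0.999),
        h2=st.floats(0.05, 0.95),
        n=st.integers(10, 10**6),
    )
    def test_symmetric_in_allele_label(self, p, h2, n):
        # depends on p only through p(1-p)
        a = ratio_general(h2, n, 1000, p, 300.0)
        b = ratio_general(h2, n, 1000, 1.0 - p, 300.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_more_power_moves_ratio_toward_one(self):
        # below the crossing point the ratio decreases toward 1 as n h2/(1-h2) grows
        p = 0.01
        ratios = [ratio_uniform(0.5, n, 1000, p) for n in (100, 1000, 10**6, 10**9)]
        assert all(r > 1 for r in ratios)
        assert ratios == sorted(ratios, reverse=True)
        assert ratios[-1] == pytest.approx(1.0, abs=1e-3)

    def test_agrees_with_single_locus_ridge_pair(self, uniform_dataset):
        # oracle: the two explicit scalar ridge estimates per locus, using the
        # realized crossproducts of a linkage-equilibrium simulation
        _, X = uniform_dataset
        p = X.p
        sum_2pq = float(np.sum(2 * p * (1 - p)))
        n, N = X.n_individuals, X.n_snps
        z2 = ((X.values - 2 * p) ** 2).sum(axis=0)
        lam_c = sum_2pq  # sigma_e2 / (sigma_a2 / sum_2pq) at h2 = 0.5
        lam_cs = float(N)
        empirical = (z2 + lam_c) / (z2 + lam_cs * 2 * p * (1 - p))
        theoretical = ratio_general(0.5, n, N, p, sum_2pq)
        rel = np.abs(empirical - theoretical) / theoretical
        assert np.median(rel) < 0.05


class TestScenarioRatios:
    def test_uniform_extremes_at_maf_half(self):
        assert round(ratio_uniform(0.2, 1000, 15_000_000, 0.5), 2) == 0.67
        assert round(ratio_uniform(0.8, 100_000, 50_000, 0.5), 2) == 0.96

    def test_ushaped_extremes_at_maf_half(self):
        assert round(ratio_ushaped(0.2, 100_000, 15_000_000, 0.5, USHAPED), 2) == 0.16
        assert round(ratio_ushaped(0.8, 100_000, 50_000, 0.5, USHAPED), 2) == 0.91

    def test_ushaped_small_cohort_range(self):
        vals = [
            ratio_ushaped(h2, 1000, N, 0.5, USHAPED)
            for h2 in (0.2, 0.8)
            for N in (50_000, 800_000, 15_000_000)
        ]
        assert round(min(vals), 2) == 0.24
        assert round(max(vals), 2) == 0.30

    def test_uniform_model_rejected(self):
        with pytest.raises(ValueError):
            ratio_ushaped(0.5, 1000, 1000, 0.3, FrequencyModel("uniform"))


class TestCrossingMaf:
    def test_uniform_crossing(self):
        got = crossing_maf(FrequencyModel("uniform"), 1000)
        assert got == pytest.approx(0.5 * (1 - math.sqrt(1 / 3)), rel=1e-12)
        assert got == pytest.approx(0.2113, abs=5e-5)

    def test_ushaped_crossings(self):
        assert round(crossing_maf(USHAPED, 1000), 3) == 0.065
        assert round(crossing_maf(USHAPED, 100_000), 2) == 0.04


FIG5_SCENARIOS = [
    (h2, n, N)
    for h2 in (0.2, 0.8)
    for n in (1000, 100_000)
    for N in (50_000, 800_000, 15_000_000)
]


class TestRatioCurve:
    @pytest.mark.parametrize("h2,n,N", FIG5_SCENARIOS)
    def test_strictly_decreasing_and_crosses_one(self, h2, n, N):
        grid = np.linspace(0.001, 0.5, 400)
        for model in (FrequencyModel("uniform"), USHAPED):
            curve = ratio_curve(Scenario(h2, n, N, model), grid)
            assert (np.diff(curve.ratio) < 0).all()
            at_cross = ratio_curve(
                Scenario(h2, n, N, model), np.array([crossing_maf(model, n)])
            )
            assert at_cross.ratio[0] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("h2,n,N", FIG5_SCENARIOS)
    def test_ushaped_below_uniform_at_rare_frequencies(self, h2, n, N):
        grid = np.linspace(0.0005, 0.0099, 50)
        uni = ratio_curve(Scenario(h2, n, N, FrequencyModel("uniform")), grid)
        ush = ratio_curve(Scenario(h2, n, N, USHAPED), grid)
        assert (ush.ratio < uni.ratio).all()

    def test_grid_outside_range_rejected(self):
        with pytest.raises(ValueError):
            ratio_curve(
                Scenario(0.5, 1000, 1000), np.array([0.6])
            )
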