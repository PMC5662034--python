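"""Synthetic genotype-phenotype data with the structure the theory assumes.

The generator emulates a progeny-tested dairy-cattle evaluation: ``n``
individuals with one weighted phenotype record each (a daughter-yield-
deviation analogue whose weight is an effective daughter count, 549 on
average), and ``N`` biallelic SNPs in Hardy-Weinberg equilibrium and linkage
equilibrium, with allele frequencies drawn from either a uniform or a
U-shaped spectrum on the discrete grid p = k/(2n).

True allele substitution effects are drawn with per-locus variance
proportional to ``(2 p_j (1 - p_j))^gamma_true`` and then rescaled so the
summed per-locus genetic variance equals ``total_additive_variance``:
``gamma_true = 0`` makes all effect variances equal (the prior of the
centered-count model) and ``gamma_true = -1`` makes every locus contribute
equal expected genetic variance (the prior of the centered-and-scaled
model), so recovery of ``gamma_true`` by the scaling scan is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .blup import PhenotypeSet
from .coding import GenotypeMatrix
from .theory import FrequencyModel

__all__ = [
    "SimulationConfig",
    "TrueEffects",
    "SimulatedDataset",
    "sample_allele_frequencies",
    "sample_genotypes",
    "simulate_true_effects",
    "sample_weights",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated dataset.

    Defaults mirror the study setting the generator stands in for where one
    is stated (mean weight 549 effective daughters, U-shaped spectrum with
    Ne = 65 and v = 1e-8); the remaining values are modest defaults chosen
    for a dataset a single workstation fits in seconds.
    """

    n_individuals: int = 500
    n_snps: int = 2000
    h2: float = 0.5
    gamma_true: float = 0.0
    total_additive_variance: float = 1.0
    mean_weight: float = 549.0
    weight_model: Literal["constant", "poisson-like"] = "constant"
    intercept: float = 0.0
    seed: int = 0
    frequency_model: FrequencyModel = field(
        default_factory=lambda: FrequencyModel("uniform")
    )

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie strictly between 0 and 1")
        if not -1.0 <= self.gamma_true <= 0.0:
            raise ValueError("gamma_true must lie in [-1, 0]")
        if self.total_additive_variance <= 0:
            raise ValueError("total_additive_variance must be positive")
        if self.mean_weight < 1:
            raise ValueError("mean_weight must be >= 1")


@dataclass
class TrueEffects:
    """True per-locus allele substitution effects and their sampling variances."""

    effects: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.effects.shape != self.variances.shape:
            raise ValueError("effects and variances must have the same length")


@dataclass
class SimulatedDataset:
    """Everything one replicate produced, truth included for oracle tests."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeSet
    true_effects: TrueEffects
    true_frequencies: np.ndarray
    genetic_values: np.ndarray
    config: SimulationConfig


def sample_allele_frequencies(
    model: FrequencyModel, n_snps: int, n_individuals: int, seed: int
) -> np.ndarray:
    """Draw locus frequencies from the spectrum's discrete grid.

    Frequencies live on p = k/(2n), k = 1..2n-1, with probabilities given by
    the spectrum density — the same support the closed-form summations use.
    """
    if n_snps == 0:
        return np.array([])
    rng = np.random.default_rng(seed)
    grid = model.grid(n_individuals)
    return rng.choice(grid, size=n_snps, p=model.density(n_individuals))


def sample_genotypes(
    frequencies: np.ndarray, n_individuals: int, seed: int
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: two independent allele draws per individual."""
    frequencies = np.asarray(frequencies, dtype=float)
    if np.any((frequencies <= 0.0) | (frequencies >= 1.0)):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    values = rng.binomial(2, frequencies, size=(n_individuals, frequencies.size))
    return GenotypeMatrix(values.astype(np.int8))


def simulate_true_effects(
    frequencies: np.ndarray,
    total_additive_variance: float,
    gamma_true: float,
    seed: int,
) -> TrueEffects:
    """Zero-mean effects with Var(effect_j) ∝ (2 p_j (1-p_j))^gamma_true.

    After sampling-variance normalisation, sum_j 2 p_j (1-p_j) Var_j equals
    ``total_additive_variance`` exactly (the expected genetic variance under
    Hardy-Weinberg and linkage equilibrium).
    """
    if total_additive_variance <= 0:
        raise ValueError("total_additive_variance must be positive")
    p = np.asarray(frequencies, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    het = 2.0 * p * (1.0 - p)
    raw_var = het**gamma_true
    variances = raw_var * (total_additive_variance / np.sum(het * raw_var))
    rng = np.random.default_rng(seed)
    effects = rng.normal(0.0, np.sqrt(variances))
    return TrueEffects(effects=effects, variances=variances)


def sample_weights(
    n_individuals: int,
    mean_weight: float,
    weight_model: str = "constant",
    seed: int = 0,
) -> np.ndarray:
    """Effective record counts: constant, or 1 + Poisson(mean - 1)."""
    if n_individuals == 0:
        return np.array([], dtype=int)
    if mean_weight < 1:
        raise ValueError("mean_weight must be >= 1")
    if weight_model == "constant":
        return np.full(n_individuals, int(round(mean_weight)))
    if weight_model == "poisson-like":
        rng = np.random.default_rng(seed)
        return 1 + rng.poisson(mean_weight - 1.0, size=n_individuals)
    raise ValueError(f"unknown weight model: {weight_model!r}")


def simulate_phenotypes(
    X: GenotypeMatrix,
    effects: TrueEffects,
    h2: float,
    weights: np.ndarray,
    intercept: float = 0.0,
    seed: int = 0,
    total_additive_variance: float | None = None,
) -> PhenotypeSet:
    """Phenotypes y_i = mu + sum_j (x_ij - 2 p_j) a_j + e_i.

    The residual e_i has variance ``sigma_e^2 / wt_i`` with the unit-weight
    residual variance set from the heritability:
    ``sigma_e^2 = sigma_a^2 (1 - h2) / h2``.  Genotypes are centered with
    their observed sample frequencies, matching the evaluation models.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie strictly between 0 and 1")
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    if weights.size != X.n_individuals:
        raise ValueError("weights length does not match the genotypes")
    if effects.effects.size != X.n_snps:
        raise ValueError("effects length does not match the genotypes")

    centered = X.values - 2.0 * X.p
    genetic = centered @ effects.effects
    if total_additive_variance is None:
        total_additive_variance = float(
            np.sum(2.0 * X.p * (1.0 - X.p) * effects.variances)
        )
    sigma_e2 = total_additive_variance * (1.0 - h2) / h2
    rng = np.random.default_rng(seed)
    residual = rng.normal(0.0, np.sqrt(sigma_e2 / weights))
    y = intercept + genetic + residual
    return PhenotypeSet(y=y, weights=weights, ids=list(X.sample_ids))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator for one configuration.

    All randomness derives from ``config.seed`` through independent child
    seeds, so every replicate is bitwise reproducible.
    """
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=4)
    freqs = sample_allele_frequencies(
        config.frequency_model, config.n_snps, config.n_individuals, int(seeds[0])
    )
    genotypes = sample_genotypes(freqs, config.n_individuals, int(seeds[1]))
    effects = simulate_true_effects(
        freqs, config.total_additive_variance, config.gamma_true, int(seeds[2])
    )
    weights = sample_weights(
        config.n_individuals, config.mean_weight, config.weight_model, int(seeds[3])
    )
    phenotypes = simulate_phenotypes(
        genotypes,
        effects,
        config.h2,
        weights,
        intercept=config.intercept,
        seed=int(seeds[3]) + 1,
        total_additive_variance=config.total_additive_variance,
    )
    centered = genotypes.values - 2.0 * genotypes.p
    return SimulatedDataset(
        genotypes=genotypes,
        phenotypes=phenotypes,
        true_effects=effects,
        true_frequencies=freqs,
        genetic_values=centered @ effects.effects,
        config=config,
    )
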