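"""Closed-form shrinkage-ratio theory for scaled versus unscaled allele counts.

A ridge-regression (SNP-BLUP) model shrinks every marker effect toward zero
with a common penalty ``lambda = sigma_e^2 / sigma_marker^2``.  When centered
allele counts are additionally scaled by the genotypic standard deviation
``sqrt(2 p (1 - p))``, the effective per-locus penalty changes, and with it
the amount of shrinkage applied to the allele substitution effect (ASE) of a
locus.  Treating each locus in isolation (linkage equilibrium, Hardy-Weinberg
genotype frequencies, phenotype information independent of genotype) the
ratio of the scaled-coding ASE to the unscaled-coding ASE has the closed form

    ratio(p) = (c n + S / (2 p (1 - p))) / (c n + N),   c = h2 / (1 - h2),

where ``n`` is the number of (equally informative) records, ``N`` the number
of markers and ``S = sum_j 2 p_j (1 - p_j)`` the summed heterozygosity of the
marker set.  ``S`` is ``N`` times the expected heterozygosity of the allele
frequency spectrum: 1/3 for a uniform spectrum (SNP arrays), and
``2 C* (2n - 1)`` for the U-shaped stationary spectrum of sequence variants,
with ``C*`` a closed-form approximation of the spectrum's normalising
constant that is valid when ``4 Ne v`` is negligible.

The ratio exceeds 1 for rare alleles (scaled coding shrinks them less),
crosses 1 exactly where ``2 p (1 - p)`` equals the spectrum's expected
heterozygosity, and tends to 1 as the information content ``c n`` grows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "FrequencyModel",
    "Scenario",
    "RatioCurve",
    "cstar",
    "cstar_exact",
    "expected_heterozygosity",
    "ratio_general",
    "ratio_uniform",
    "ratio_ushaped",
    "crossing_maf",
    "ratio_curve",
]

#: Euler-Mascheroni constant (20 significant digits).  This is the constant
#: appearing in the harmonic-sum approximation of the U-shaped normaliser;
#: it is unrelated to the allele-count scaling exponent, which is called
#: ``gamma`` throughout this package.
EULER_MASCHERONI = 0.57721566490153286061

# 4*Ne*v above this threshold invalidates the closed-form C* approximation;
# the exact grid summation is used instead.
_THETA_THRESHOLD = 1e-3


@dataclass(frozen=True)
class FrequencyModel:
    """Allele-frequency spectrum on the discrete grid p = k/(2n), k=1..2n-1.

    Parameters
    ----------
    kind:
        ``"uniform"`` — every segregating frequency equally likely (the
        spectrum of common-SNP arrays); ``"ushaped"`` — Wright's stationary
        mutation-drift spectrum ``phi(p) ∝ p^(4 Ne v - 1) (1-p)^(4 Ne v - 1)``
        with zero selection, typical of whole-genome sequence variants.
    ne:
        Effective population size (U-shaped only).
    mutation_rate:
        Per-generation mutation probability ``v``; the forward and backward
        rates are assumed equal (U-shaped only).
    selection_coefficient:
        Kept for clarity of the model's scope; must be 0.  The selection
        term ``exp(4 Ne s p (1-p))`` of the full stationary density is
        outside this model.
    """

    kind: Literal["uniform", "ushaped"]
    ne: int = 65
    mutation_rate: float = 1e-8
    selection_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "ushaped"):
            raise ValueError(f"unknown frequency model kind: {self.kind!r}")
        if self.kind == "ushaped":
            if self.selection_coefficient != 0.0:
                raise ValueError(
                    "the U-shaped model is implemented for selection_coefficient=0 only"
                )
            if self.ne <= 0 or self.mutation_rate <= 0:
                raise ValueError("ne and mutation_rate must be positive")

    @property
    def theta(self) -> float:
        """Scaled mutation rate 4*Ne*v (0 for the uniform model)."""
        if self.kind == "uniform":
            return 0.0
        return 4.0 * self.ne * self.mutation_rate

    def grid(self, n_individuals: int) -> np.ndarray:
        """Segregating frequencies 1/(2n), ..., (2n-1)/(2n)."""
        if n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        two_n = 2 * n_individuals
        return np.arange(1, two_n) / two_n

    def density(self, n_individuals: int) -> np.ndarray:
        """Probability mass of each grid frequency; sums to 1."""
        p = self.grid(n_individuals)
        if self.kind == "uniform":
            w = np.ones_like(p)
        else:
            e = self.theta - 1.0
            # log-space for numerical safety near the boundaries
            w = np.exp(e * (np.log(p) + np.log1p(-p)))
        return w / w.sum()


@dataclass(frozen=True)
class Scenario:
    """One theoretical setting: heritability, records, markers, spectrum."""

    h2: float
    n_individuals: int
    n_snps: int
    frequency_model: FrequencyModel = field(
        default_factory=lambda: FrequencyModel("uniform")
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie strictly between 0 and 1")
        if self.n_individuals < 2 or self.n_snps < 1:
            raise ValueError("n_individuals >= 2 and n_snps >= 1 required")


@dataclass(frozen=True)
class RatioCurve:
    """Theoretical ASE ratio (scaled/unscaled) tabulated over frequencies."""

    p_grid: np.ndarray
    ratio: np.ndarray
    scenario: Scenario


def cstar(n_individuals: int) -> float:
    """Closed-form approximation of the U-shaped normalising constant.

    ``C* = (1/4n) * (ln(2n - 1) + 1/(4n - 2) + gamma_EM)^(-1)`` where
    ``gamma_EM`` is the Euler-Mascheroni constant.  Valid when 4*Ne*v is
    negligible, in which case the exact normaliser is the reciprocal of a
    harmonic sum which the logarithmic expression approximates.
    """
    n = int(n_individuals)
    if n < 2:
        raise ValueError("n_individuals must be >= 2")
    return 1.0 / (4.0 * n) / (math.log(2 * n - 1) + 1.0 / (4 * n - 2) + EULER_MASCHERONI)


def cstar_exact(n_individuals: int) -> float:
    """Exact zero-mutation-limit normaliser 1 / (4 n H_{2n-1}).

    The grid sum of ``1 / (p (1 - p))`` over p = k/(2n) telescopes into the
    harmonic number ``H_{2n-1}``; this is the quantity ``cstar`` approximates.
    """
    n = int(n_individuals)
    if n < 2:
        raise ValueError("n_individuals must be >= 2")
    harmonic = np.sum(1.0 / np.arange(1, 2 * n)) if n <= 10**6 else (
        math.log(2 * n - 1) + EULER_MASCHERONI + 1.0 / (2 * (2 * n - 1))
    )
    return 1.0 / (4.0 * n * harmonic)


def expected_heterozygosity(model: FrequencyModel, n_individuals: int) -> float:
    """Mean of 2p(1-p) under the spectrum: E[2p(1-p)] = sum 2p(1-p) phi(p).

    Uniform spectrum: exactly 1/3 (continuous limit of the grid sum).
    U-shaped spectrum: ``2 C* (2n - 1)`` via the closed-form normaliser when
    4*Ne*v is negligible, otherwise the exact grid summation.
    """
    if model.kind == "uniform":
        return 1.0 / 3.0
    if model.theta < _THETA_THRESHOLD:
        return 2.0 * cstar(n_individuals) * (2 * n_individuals - 1)
    warnings.warn(
        f"4*Ne*v = {model.theta:.3g} is not negligible; "
        "using exact grid summation instead of the C* approximation",
        stacklevel=2,
    )
    p = model.grid(n_individuals)
    phi = model.density(n_individuals)
    return float(np.sum(2.0 * p * (1.0 - p) * phi))


def ratio_general(
    h2: float,
    n_individuals: int,
    n_snps: int,
    p_j: float | np.ndarray,
    sum_2pq: float,
) -> float | np.ndarray:
    """Single-locus ASE ratio (scaled / unscaled coding).

    ``ratio = (c n + S / (2 p (1-p))) / (c n + N)`` with ``c = h2/(1-h2)``
    and ``S = sum_2pq`` the summed heterozygosity of the marker set.  Depends
    on the locus only through ``p (1 - p)`` and equals 1 exactly where
    ``2 p (1-p) = S / N``.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie strictly between 0 and 1")
    if sum_2pq <= 0:
        raise ValueError("sum_2pq must be positive")
    p = np.asarray(p_j, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    c_n = h2 / (1.0 - h2) * n_individuals
    out = (c_n + sum_2pq / (2.0 * p * (1.0 - p))) / (c_n + n_snps)
    return float(out) if np.isscalar(p_j) else out


def ratio_uniform(
    h2: float, n_individuals: int, n_snps: int, p_j: float | np.ndarray
) -> float | np.ndarray:
    """ASE ratio under a uniform spectrum: summed heterozygosity N/3."""
    return ratio_general(h2, n_individuals, n_snps, p_j, n_snps / 3.0)


def ratio_ushaped(
    h2: float,
    n_individuals: int,
    n_snps: int,
    p_j: float | np.ndarray,
    model: FrequencyModel | None = None,
) -> float | np.ndarray:
    """ASE ratio under the U-shaped spectrum: S = N * 2 C* (2n - 1)."""
    if model is None:
        model = FrequencyModel("ushaped")
    if model.kind != "ushaped":
        raise ValueError("ratio_ushaped requires a ushaped frequency model")
    het = expected_heterozygosity(model, n_individuals)
    return ratio_general(h2, n_individuals, n_snps, p_j, n_snps * het)


def crossing_maf(model: FrequencyModel, n_individuals: int) -> float:
    """Frequency in (0, 0.5] at which the ASE ratio equals 1.

    Solves ``2 p (1 - p) = E[2p(1-p)]`` in closed form:
    ``p = (1 - sqrt(1 - 2 E)) / 2``.  Independent of h2, n and N beyond the
    dependence of E on the spectrum (and on n for the U-shaped spectrum).
    """
    het = expected_heterozygosity(model, n_individuals)
    if het >= 0.5:
        raise ValueError("expected heterozygosity >= 0.5: no crossing in (0, 0.5]")
    return 0.5 * (1.0 - math.sqrt(1.0 - 2.0 * het))


def ratio_curve(scenario: Scenario, p_grid: np.ndarray) -> RatioCurve:
    """Tabulate the theoretical ratio over a frequency grid for a scenario."""
    p = np.asarray(p_grid, dtype=float)
    if np.any((p <= 0.0) | (p > 0.5)):
        raise ValueError("p_grid must lie in (0, 0.5]")
    model = scenario.frequency_model
    if model.kind == "uniform":
        r = ratio_uniform(scenario.h2, scenario.n_individuals, scenario.n_snps, p)
    else:
        r = ratio_ushaped(
            scenario.h2, scenario.n_individuals, scenario.n_snps, p, model
        )
    return RatioCurve(p_grid=p, ratio=np.asarray(r), scenario=scenario)
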