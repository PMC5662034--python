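"""Genotype containers, variant filters, centered/scaled coding and the GRM.

Genotypes are allele counts ``x_ij`` in {0, 1, 2} of a designated counted
allele.  Coding subtracts the mean count ``2 p_j`` and multiplies by
``(2 p_j (1 - p_j))^(gamma/2)``: ``gamma = 0`` is plain centering (the Z
matrix, VanRaden method 1 when crossed into a relationship matrix) and
``gamma = -1`` centers and scales each locus to unit variance under
Hardy-Weinberg proportions (the W matrix, VanRaden method 2).  The genomic
relationship matrix for any gamma divides the coded crossproduct by
``s_gamma = sum_j (2 p_j (1-p_j))^(gamma+1)``, the unique divisor that keeps
marker-level ridge regression with per-marker variance
``sigma_a^2 / s_gamma`` equivalent to the individual-level GBLUP model and
that reduces to the two VanRaden divisors at the endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "CodedMatrix",
    "allele_frequency",
    "apply_variant_filters",
    "code_genotypes",
    "scale_sum",
    "build_grm",
    "ase_transform",
    "ase_inverse_transform",
]


@dataclass
class GenotypeMatrix:
    """Integer allele counts (individuals x loci) with locus frequencies.

    ``p`` is the observed sample frequency of the counted allele, i.e. the
    column mean divided by 2; it is recomputed whenever loci are subset.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    variant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        if self.values.size and not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("genotype values must be allele counts in {0, 1, 2}")
        self.values = self.values.astype(np.int8, copy=False)
        n, m = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"id{i + 1}" for i in range(n)]
        if not self.variant_ids:
            self.variant_ids = [f"snp{j + 1}" for j in range(m)]
        if len(self.sample_ids) != n or len(self.variant_ids) != m:
            raise ValueError("id lengths do not match the genotype matrix shape")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def p(self) -> np.ndarray:
        """Per-locus frequency of the counted allele."""
        return allele_frequency(self)

    @property
    def maf(self) -> np.ndarray:
        p = self.p
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeMatrix(
            self.values[:, idx],
            sample_ids=list(self.sample_ids),
            variant_ids=[self.variant_ids[j] for j in idx],
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeMatrix(
            self.values[idx, :],
            sample_ids=[self.sample_ids[i] for i in idx],
            variant_ids=list(self.variant_ids),
        )


@dataclass
class CodedMatrix:
    """Centered (and possibly scaled) allele counts tied to a scaling gamma.

    ``values[i, j] = (x_ij - 2 p_j) * (2 p_j (1 - p_j))^(gamma/2)`` and
    ``s_gamma = sum_j (2 p_j (1-p_j))^(gamma+1)`` is the matching GRM divisor.
    """

    values: np.ndarray
    gamma: float
    freq_used: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    variant_ids: list[str] = field(default_factory=list)

    @property
    def s_gamma(self) -> float:
        return scale_sum(self.freq_used, self.gamma)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


def allele_frequency(X: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Observed frequency of the counted allele: column mean count / 2."""
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X)
    if values.size == 0:
        raise ValueError("cannot compute allele frequencies of an empty matrix")
    return values.mean(axis=0) / 2.0


def apply_variant_filters(
    X: GenotypeMatrix,
    min_minor_copies: int = 5,
    require_all_genotypes: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci with too few minor-allele copies or missing genotype classes.

    A locus is retained when it carries at least ``min_minor_copies`` copies
    of its minor allele and, if ``require_all_genotypes``, at least one
    heterozygote and one minor-allele homozygote are observed.  Returns the
    filtered matrix (frequencies recompute automatically on the retained
    loci) and a removal report with one row per dropped locus.  The filter is
    idempotent.
    """
    values = X.values
    n = X.n_individuals
    alt_copies = values.sum(axis=0)
    minor_copies = np.minimum(alt_copies, 2 * n - alt_copies)
    het_count = (values == 1).sum(axis=0)
    # the minor-allele homozygote class: counted-allele homozygote when the
    # counted allele is minor, reference homozygote otherwise
    minor_is_alt = alt_copies <= 2 * n - alt_copies
    minor_hom = np.where(minor_is_alt, (values == 2).sum(axis=0), (values == 0).sum(axis=0))

    reasons: list[tuple[str, str]] = []
    keep = np.ones(X.n_snps, dtype=bool)
    for j in range(X.n_snps):
        if minor_copies[j] == 0:
            keep[j] = False
            reasons.append((X.variant_ids[j], "monomorphic"))
        elif minor_copies[j] < min_minor_copies:
            keep[j] = False
            reasons.append(
                (X.variant_ids[j], f"minor_copies<{min_minor_copies}")
            )
        elif require_all_genotypes and (het_count[j] == 0 or minor_hom[j] == 0):
            keep[j] = False
            reasons.append((X.variant_ids[j], "missing_genotype_class"))
    report = pd.DataFrame(reasons, columns=["variant_id", "reason"])
    return X.subset_variants(keep), report


def code_genotypes(
    X: GenotypeMatrix | np.ndarray,
    gamma: float = 0.0,
    freqs: np.ndarray | None = None,
) -> CodedMatrix:
    """Center and gamma-scale allele counts.

    ``freqs`` overrides the observed frequencies (e.g. to code a validation
    set with training or full-data frequencies).  Loci fixed at p = 0 or 1
    are rejected: the scaling is undefined and a fixed locus carries no
    information anyway.
    """
    if not -1.0 <= gamma <= 0.0:
        raise ValueError("gamma must lie in [-1, 0]")
    if isinstance(X, GenotypeMatrix):
        values, sample_ids, variant_ids = X.values, X.sample_ids, X.variant_ids
    else:
        values = np.asarray(X)
        sample_ids, variant_ids = [], []
    p = allele_frequency(values) if freqs is None else np.asarray(freqs, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError(
            "allele frequencies must lie strictly in (0, 1); "
            "remove monomorphic loci first"
        )
    het = 2.0 * p * (1.0 - p)
    coded = (values - 2.0 * p) * het ** (gamma / 2.0)
    return CodedMatrix(
        values=coded,
        gamma=float(gamma),
        freq_used=p,
        sample_ids=list(sample_ids),
        variant_ids=list(variant_ids),
    )


def scale_sum(p: np.ndarray, gamma: float) -> float:
    """GRM divisor s_gamma = sum_j (2 p_j (1 - p_j))^(gamma + 1).

    Equals sum_j 2 p_j (1 - p_j) at gamma = 0 and the marker count N at
    gamma = -1.
    """
    het = 2.0 * np.asarray(p, dtype=float) * (1.0 - np.asarray(p, dtype=float))
    return float(np.sum(het ** (gamma + 1.0)))


def build_grm(M: CodedMatrix) -> np.ndarray:
    """Genomic relationship matrix G = M M' / s_gamma."""
    s = M.s_gamma
    if s <= 0:
        raise ValueError("scale sum s_gamma must be positive")
    return (M.values @ M.values.T) / s


def ase_transform(
    b_hat: np.ndarray, p: np.ndarray, gamma: float
) -> np.ndarray:
    """Map coded-scale effects to allele substitution effects.

    ``ase_j = b_j * (2 p_j (1-p_j))^(gamma/2)``: the identity at gamma = 0,
    division by the genotypic standard deviation at gamma = -1 (the diagonal
    U-matrix transformation).
    """
    b_hat = np.asarray(b_hat, dtype=float)
    p = np.asarray(p, dtype=float)
    if b_hat.shape != p.shape:
        raise ValueError("b_hat and p must have the same length")
    het = 2.0 * p * (1.0 - p)
    return b_hat * het ** (gamma / 2.0)


def ase_inverse_transform(
    ase: np.ndarray, p: np.ndarray, gamma: float
) -> np.ndarray:
    """Map allele substitution effects back to coded-scale effects."""
    ase = np.asarray(ase, dtype=float)
    p = np.asarray(p, dtype=float)
    het = 2.0 * p * (1.0 - p)
    return ase * het ** (-gamma / 2.0)
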