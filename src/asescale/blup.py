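"""Weighted SNP-BLUP / GBLUP fitting, REML variance components, ASE back-solving.

The model is the weighted random-regression ridge model

    y = 1 mu + M b + e,   b ~ N(0, I sigma_a^2 / s_gamma),
                          e ~ N(0, D sigma_e^2),  D = diag(1 / wt_i),

where ``M`` holds gamma-coded allele counts and ``wt_i`` is the effective
record count behind phenotype ``i`` (the number of daughters for a
daughter-yield-deviation phenotype).  With the genomic relationship matrix
``G = M M' / s_gamma`` the model is identical to the individual-level GBLUP
model ``y = 1 mu + g + e`` with ``g ~ N(0, G sigma_a^2)``; marker effects are
recovered from the individual solutions by back-solving.  Variance
components are estimated by restricted maximum likelihood (REML) through a
single spectral decomposition of the weight-folded relationship matrix,
which reduces every likelihood evaluation to O(n) and makes the fit
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .coding import (
    CodedMatrix,
    GenotypeMatrix,
    ase_transform,
    build_grm,
    code_genotypes,
)

__all__ = [
    "VarianceComponents",
    "PhenotypeSet",
    "FitResult",
    "solve_snp_blup",
    "fit_greml",
    "backsolve_ase",
    "reml_loglik",
    "SNPBLUP",
]

# bounded search window for ln(sigma_a^2 / sigma_e^2) in REML
_LOG_RATIO_BOUNDS = (-10.0, 10.0)
_TINY = 1e-300


@dataclass(frozen=True)
class VarianceComponents:
    """Additive and residual variance of the weighted model.

    ``sigma_e2`` is the residual variance of a record with unit weight; a
    record with weight ``wt`` has residual variance ``sigma_e2 / wt``.
    """

    sigma_a2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)

    def snp_variance(self, s_gamma: float) -> float:
        """Per-marker effect variance sigma_a^2 / s_gamma on the coded scale."""
        return self.sigma_a2 / s_gamma

    def ridge_lambda(self, s_gamma: float) -> float:
        """Ridge penalty lambda = sigma_e^2 / (sigma_a^2 / s_gamma)."""
        if self.sigma_a2 <= 0:
            raise ValueError("ridge penalty undefined for sigma_a2 = 0")
        return self.sigma_e2 * s_gamma / self.sigma_a2


@dataclass
class PhenotypeSet:
    """Weighted phenotypes: one record per individual with a record count."""

    y: np.ndarray
    weights: np.ndarray | None = None
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.weights is None:
            self.weights = np.ones_like(self.y)
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.weights.shape != self.y.shape:
            raise ValueError("weights and phenotypes must have the same length")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")
        if not self.ids:
            self.ids = [f"id{i + 1}" for i in range(self.y.size)]
        if len(self.ids) != self.y.size:
            raise ValueError("ids length does not match phenotypes")

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class FitResult:
    """Solutions of one SNP-BLUP/GBLUP fit at a fixed scaling gamma."""

    mu_hat: float
    b_hat: np.ndarray
    ase: np.ndarray
    dgv: np.ndarray
    varcomp: VarianceComponents
    logL_reml: float
    gamma: float
    freq_used: np.ndarray

    @property
    def predicted(self) -> np.ndarray:
        """Predicted phenotypes DGV + mu."""
        return self.dgv + self.mu_hat


class _SpectralREML:
    """Profiled restricted likelihood of y = 1 mu + g + e via one eigendecomposition.

    Folding the weights into the model with ``D^(-1/2)`` and rotating by the
    eigenvectors of the folded relationship matrix diagonalises the
    covariance, so each evaluation in the variance-ratio search is O(n).
    """

    def __init__(self, G: np.ndarray, y: np.ndarray, weights: np.ndarray) -> None:
        sqrt_w = np.sqrt(weights)
        G_fold = G * np.outer(sqrt_w, sqrt_w)
        # symmetrise against accumulated round-off before eigendecomposition
        s, U = np.linalg.eigh((G_fold + G_fold.T) / 2.0)
        self.eigvals = np.clip(s, 0.0, None)
        self.ystar = U.T @ (sqrt_w * y)
        self.xstar = U.T @ sqrt_w
        self.n = y.size
        self.log_det_weights = float(np.sum(np.log(weights)))

    def _quadratics(self, sigma_a2: float, sigma_e2: float):
        v = sigma_a2 * self.eigvals + sigma_e2
        xvx = float(np.sum(self.xstar**2 / v))
        xvy = float(np.sum(self.xstar * self.ystar / v))
        yvy = float(np.sum(self.ystar**2 / v))
        return v, xvx, xvy, yvy

    def loglik(self, sigma_a2: float, sigma_e2: float) -> float:
        """Restricted log-likelihood at the given components.

        Includes all constants (for an intercept-only fixed design), so the
        value matches a dense evaluation of
        -1/2 [ (n-1) ln 2pi + ln|V| + ln|X'V^-1 X| + y'Py ].
        """
        v, xvx, xvy, yvy = self._quadratics(sigma_a2, sigma_e2)
        ypy = yvy - xvy**2 / xvx
        log_det_v = float(np.sum(np.log(v))) - self.log_det_weights
        return -0.5 * (
            (self.n - 1) * math.log(2.0 * math.pi)
            + log_det_v
            + math.log(max(xvx, _TINY))
            + ypy
        )

    def profile(self, log_ratio: float):
        """Profile sigma_total out at a fixed ln(sigma_a^2/sigma_e^2)."""
        ratio = math.exp(log_ratio)
        # unit-scale components sigma_a2 = r/(1+r), sigma_e2 = 1/(1+r)
        sa, se = ratio / (1.0 + ratio), 1.0 / (1.0 + ratio)
        v, xvx, xvy, yvy = self._quadratics(sa, se)
        ypy = yvy - xvy**2 / xvx
        scale = max(ypy / (self.n - 1), _TINY)
        log_det_v = float(np.sum(np.log(v))) - self.log_det_weights
        loglik = -0.5 * (
            (self.n - 1) * (math.log(2.0 * math.pi) + math.log(scale) + 1.0)
            + log_det_v
            + math.log(max(xvx, _TINY))
        )
        return loglik, sa * scale, se * scale

    def solve_mu(self, sigma_a2: float, sigma_e2: float) -> float:
        _, xvx, xvy, _ = self._quadratics(sigma_a2, sigma_e2)
        return xvy / xvx


def fit_greml(
    G: np.ndarray,
    pheno: PhenotypeSet,
    tol: float = 1e-8,
) -> tuple[VarianceComponents, float]:
    """REML estimates of (sigma_a^2, sigma_e^2) for the single-GRM model.

    Deterministic bounded Brent search over the log variance ratio in
    [-10, 10]; returns the components and the restricted log-likelihood at
    the optimum.  Raises if ``G`` is not symmetric positive semi-definite
    within tolerance.
    """
    G = np.asarray(G, dtype=float)
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("relationship matrix must be symmetric")
    if G.shape[0] != pheno.n:
        raise ValueError("relationship matrix does not match the phenotypes")
    reml = _SpectralREML(G, pheno.y, pheno.weights)
    if reml.eigvals[-1] <= 0:
        raise ValueError("relationship matrix has no positive eigenvalue")

    res = optimize.minimize_scalar(
        lambda t: -reml.profile(t)[0],
        bounds=_LOG_RATIO_BOUNDS,
        method="bounded",
        options={"xatol": tol},
    )
    loglik, sigma_a2, sigma_e2 = reml.profile(float(res.x))
    return VarianceComponents(sigma_a2, sigma_e2), loglik


def reml_loglik(
    G: np.ndarray, pheno: PhenotypeSet, varcomp: VarianceComponents
) -> float:
    """Restricted log-likelihood at fixed variance components.

    Comparable across coding choices (different G) because the fixed-effect
    design (an intercept) does not change.
    """
    if varcomp.sigma_a2 <= 0 or varcomp.sigma_e2 <= 0:
        raise ValueError("variances must be positive")
    reml = _SpectralREML(np.asarray(G, dtype=float), pheno.y, pheno.weights)
    return reml.loglik(varcomp.sigma_a2, varcomp.sigma_e2)


def _check_grm_matches(M: CodedMatrix, G: np.ndarray) -> None:
    trace_from_m = float(np.sum(M.values**2)) / M.s_gamma
    trace_g = float(np.trace(G))
    if not math.isclose(trace_from_m, trace_g, rel_tol=1e-6, abs_tol=1e-8):
        raise ValueError(
            "relationship matrix does not match the coded matrix "
            "(was it built with the same gamma and frequencies?)"
        )


def solve_snp_blup(
    M: CodedMatrix, pheno: PhenotypeSet, varcomp: VarianceComponents
) -> FitResult:
    """Solve the weighted ridge system for mu and the marker effects.

    For N <= n the marker-level mixed-model equations are solved directly;
    for N > n the equivalent n x n individual-level (GBLUP) system is solved
    and effects are recovered as ``b = (sigma_b^2/sigma_a^2) M' V^-1 (y - 1 mu)``.
    Both routes give identical solutions.
    """
    n, N = M.n_individuals, M.n_snps
    if pheno.n != n:
        raise ValueError("phenotypes do not match the coded matrix")
    s_gamma = M.s_gamma
    lam = varcomp.ridge_lambda(s_gamma)
    wt = pheno.weights
    y = pheno.y

    if N <= n:
        Z = M.values
        ZtDinv = Z.T * wt
        A = np.empty((N + 1, N + 1))
        A[0, 0] = wt.sum()
        A[0, 1:] = wt @ Z
        A[1:, 0] = A[0, 1:]
        A[1:, 1:] = ZtDinv @ Z + lam * np.eye(N)
        rhs = np.concatenate(([wt @ y], ZtDinv @ y))
        try:
            sol = linalg.solve(A, rhs, assume_a="sym")
        except linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise linalg.LinAlgError(
                f"singular mixed-model equations (lambda={lam:.3g})"
            ) from exc
        mu_hat, b_hat = float(sol[0]), sol[1:]
    else:
        sigma_b2 = varcomp.snp_variance(s_gamma)
        V = sigma_b2 * (M.values @ M.values.T) + np.diag(varcomp.sigma_e2 / wt)
        try:
            cho = linalg.cho_factor(V)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError("phenotypic covariance V is singular") from exc
        ones = np.ones(n)
        Vinv_1 = linalg.cho_solve(cho, ones)
        Vinv_y = linalg.cho_solve(cho, y)
        mu_hat = float(ones @ Vinv_y) / float(ones @ Vinv_1)
        b_hat = sigma_b2 * (M.values.T @ linalg.cho_solve(cho, y - mu_hat))

    dgv = M.values @ b_hat
    ase = ase_transform(b_hat, M.freq_used, M.gamma)
    G = build_grm(M)
    logL = reml_loglik(G, pheno, varcomp)
    return FitResult(
        mu_hat=mu_hat,
        b_hat=b_hat,
        ase=ase,
        dgv=dgv,
        varcomp=varcomp,
        logL_reml=logL,
        gamma=M.gamma,
        freq_used=M.freq_used,
    )


def backsolve_ase(
    M: CodedMatrix,
    G: np.ndarray,
    dgv: np.ndarray,
    varcomp: VarianceComponents | None = None,
) -> np.ndarray:
    """Recover allele substitution effects from individual genomic values.

    ``b = (1/s_gamma) M' G^-1 dgv`` followed by the coded-to-ASE transform.
    A pseudo-inverse (relative cutoff 1e-10) is used when G is singular,
    which is the rule rather than the exception when n exceeds the matrix
    rank.  Equals the directly estimated ASE from :func:`solve_snp_blup`
    for the same data and components.
    """
    G = np.asarray(G, dtype=float)
    dgv = np.asarray(dgv, dtype=float)
    _check_grm_matches(M, G)
    eigvals = np.linalg.eigvalsh((G + G.T) / 2.0)
    if eigvals[-1] <= 0:
        raise ValueError("relationship matrix has no positive eigenvalue")
    if eigvals[0] > 1e-10 * eigvals[-1]:
        g_inv_dgv = linalg.solve(G, dgv, assume_a="pos")
    else:
        g_inv_dgv = linalg.pinvh(G, rtol=1e-10) @ dgv
    b_hat = (M.values.T @ g_inv_dgv) / M.s_gamma
    return ase_transform(b_hat, M.freq_used, M.gamma)


class SNPBLUP(RegressorMixin, BaseEstimator):
    """Weighted SNP-BLUP / GBLUP genomic evaluation at a fixed scaling gamma.

    Parameters
    ----------
    gamma:
        Allele-count scaling exponent in [-1, 0]: coded values are
        ``(x - 2p) (2p(1-p))^(gamma/2)``.  0 centers only (RRc), -1 centers
        and scales to unit variance (RRcs).
    h2:
        If given, fixes the variance ratio at ``h2/(1-h2)`` and profiles
        only the total variance; if None, both components are estimated by
        REML.
    sigma_a2, sigma_e2:
        If both given, variance components are fixed and no REML is run.

    Attributes
    ----------
    intercept_ : float
        Estimated general mean.
    coef_ : ndarray of shape (n_snps,)
        Effects on the coded scale.
    ase_ : ndarray of shape (n_snps,)
        Allele substitution effects (trait units per counted-allele copy).
    dgv_ : ndarray of shape (n_individuals,)
        Direct genomic values of the training individuals (excludes the
        intercept).
    p_ : ndarray of shape (n_snps,)
        Counted-allele frequencies used for coding.
    varcomp_ : VarianceComponents
    loglik_ : float
        Restricted log-likelihood at the fitted components.

    Examples
    --------
    >>> est = SNPBLUP(gamma=-1.0).fit(dosages, y, sample_weight=wt)
    >>> est.predict(new_dosages)  # mu + sum_j (x_j - 2 p_j) * ase_j
    """

    def __init__(
        self,
        gamma: float = 0.0,
        h2: float | None = None,
        sigma_a2: float | None = None,
        sigma_e2: float | None = None,
    ) -> None:
        self.gamma = gamma
        self.h2 = h2
        self.sigma_a2 = sigma_a2
        self.sigma_e2 = sigma_e2

    def _resolve_varcomp(
        self, G: np.ndarray, pheno: PhenotypeSet
    ) -> tuple[VarianceComponents, float]:
        if self.sigma_a2 is not None and self.sigma_e2 is not None:
            vc = VarianceComponents(self.sigma_a2, self.sigma_e2)
            return vc, reml_loglik(G, pheno, vc)
        if self.h2 is not None:
            if not 0.0 < self.h2 < 1.0:
                raise ValueError("h2 must lie strictly between 0 and 1")
            reml = _SpectralREML(G, pheno.y, pheno.weights)
            loglik, sa, se = reml.profile(math.log(self.h2 / (1.0 - self.h2)))
            return VarianceComponents(sa, se), loglik
        return fit_greml(G, pheno)

    def fit(self, X, y, sample_weight=None):
        """Fit on an (n_individuals, n_snps) dosage matrix or GenotypeMatrix."""
        if isinstance(X, GenotypeMatrix):
            dosages = X.values
        else:
            dosages = np.asarray(X)
            if dosages.ndim != 2:
                raise ValueError("X must be a 2-D dosage matrix")
        y = np.asarray(y, dtype=float).ravel()
        if y.size != dosages.shape[0]:
            raise ValueError("y length does not match X")
        pheno = PhenotypeSet(y=y, weights=sample_weight)

        M = code_genotypes(dosages, gamma=self.gamma)
        G = build_grm(M)
        varcomp, loglik = self._resolve_varcomp(G, pheno)
        result = solve_snp_blup(M, pheno, varcomp)

        self.n_features_in_ = dosages.shape[1]
        self.p_ = M.freq_used
        self.s_gamma_ = M.s_gamma
        self.intercept_ = result.mu_hat
        self.coef_ = result.b_hat
        self.ase_ = result.ase
        self.dgv_ = result.dgv
        self.varcomp_ = varcomp
        self.loglik_ = loglik
        self.result_ = result
        return self

    def predict(self, X):
        """Predicted phenotype mu + DGV for (possibly new) individuals.

        New dosages are centered with the training allele frequencies; the
        DGV is the centered count times the ASE summed over loci.
        """
        check_is_fitted(self, "ase_")
        dosages = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X)
        if dosages.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of loci than the fit")
        centered = dosages - 2.0 * self.p_
        return self.intercept_ + centered @ self.ase_
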