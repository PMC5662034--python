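"""Scan of the allele-count scaling exponent gamma over [-1, 0].

Two selection criteria are computed on a grid of gamma values (step 0.1 by
default): the restricted log-likelihood of the model on the full data, and
the weighted mean squared error of prediction (MSEP) on a train/validation
split of the individuals.  Variance components are re-estimated by REML at
every grid point.  The grid endpoints reproduce the standalone
centered-only (gamma = 0) and centered-and-scaled (gamma = -1) fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .blup import PhenotypeSet, VarianceComponents, fit_greml
from .coding import GenotypeMatrix, allele_frequency, build_grm, code_genotypes

__all__ = [
    "SplitSpec",
    "ScanResult",
    "default_gamma_grid",
    "split",
    "msep",
    "scan_loglik",
    "scan_msep",
    "GammaScan",
]


def default_gamma_grid(step: float = 0.1) -> np.ndarray:
    """Grid from -1 to 0 inclusive, rounded to avoid float drift."""
    n_steps = int(round(1.0 / step))
    return np.round(np.linspace(-1.0, 0.0, n_steps + 1), 10)


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation partition of the individuals.

    ``by_order`` uses the input order as the age proxy (the first
    ``train_fraction`` of individuals train, the rest validate), mirroring
    an older-bulls/younger-bulls split.  ``by_id_list`` takes explicit ids.
    """

    rule: Literal["by_order", "by_id_list"] = "by_order"
    train_fraction: float | None = None
    train_ids: tuple[str, ...] = ()
    validation_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rule == "by_order":
            if self.train_fraction is None or not 0.0 < self.train_fraction < 1.0:
                raise ValueError(
                    "by_order requires train_fraction strictly between 0 and 1"
                )
        elif self.rule == "by_id_list":
            if not self.train_ids or not self.validation_ids:
                raise ValueError("by_id_list requires both id lists")
            if set(self.train_ids) & set(self.validation_ids):
                raise ValueError("train and validation ids overlap")
        else:
            raise ValueError(f"unknown split rule: {self.rule!r}")


@dataclass
class ScanResult:
    """Per-gamma criteria and the optimum of each."""

    gamma_grid: np.ndarray
    logL: np.ndarray | None = None
    msep: np.ndarray | None = None

    def _best(self, values: np.ndarray, maximize: bool) -> float:
        finite = np.isfinite(values)
        if not finite.any():
            raise ValueError("no grid point produced a finite criterion")
        vals = np.where(finite, values, -np.inf if maximize else np.inf)
        best = vals.max() if maximize else vals.min()
        # ties broken toward the more negative gamma (grid is sorted)
        return float(self.gamma_grid[np.flatnonzero(vals == best)[0]])

    @property
    def best_gamma_logL(self) -> float:
        if self.logL is None:
            raise ValueError("log-likelihood scan was not run")
        return self._best(self.logL, maximize=True)

    @property
    def best_gamma_msep(self) -> float:
        if self.msep is None:
            raise ValueError("MSEP scan was not run")
        return self._best(self.msep, maximize=False)

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"gamma": self.gamma_grid}
        if self.logL is not None:
            data["logL"] = self.logL
        if self.msep is not None:
            data["msep"] = self.msep
        return pd.DataFrame(data)


def split(pheno: PhenotypeSet, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (train, validation): disjoint and jointly exhaustive."""
    n = pheno.n
    if spec.rule == "by_order":
        n_train = int(round(spec.train_fraction * n))
        if n_train == 0 or n_train == n:
            raise ValueError("split leaves an empty partition")
        return np.arange(n_train), np.arange(n_train, n)
    index = {sid: i for i, sid in enumerate(pheno.ids)}
    try:
        train = np.array([index[s] for s in spec.train_ids])
        val = np.array([index[s] for s in spec.validation_ids])
    except KeyError as exc:
        raise ValueError(f"id not present in the phenotypes: {exc}") from exc
    if len(train) + len(val) != n:
        raise ValueError("split does not cover all individuals")
    return train, val


def msep(predicted: np.ndarray, observed: np.ndarray, weights: np.ndarray) -> float:
    """Weighted mean squared error of prediction: sum wt (pred-obs)^2 / sum wt."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not predicted.shape == observed.shape == weights.shape:
        raise ValueError("predicted, observed and weights must have equal length")
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    return float(np.sum(weights * (predicted - observed) ** 2) / total)


def _prepare_grid(gamma_grid) -> np.ndarray:
    grid = np.unique(np.round(np.asarray(gamma_grid, dtype=float), 10))
    if grid.size == 0:
        raise ValueError("empty gamma grid")
    if grid.min() < -1.0 or grid.max() > 0.0:
        raise ValueError("gamma grid must lie within [-1, 0]")
    return grid


def scan_loglik(
    X: GenotypeMatrix,
    pheno: PhenotypeSet,
    gamma_grid=None,
) -> ScanResult:
    """REML log-likelihood of the full-data model at each gamma.

    A grid point where REML fails is recorded as NaN and the scan continues.
    """
    grid = _prepare_grid(default_gamma_grid() if gamma_grid is None else gamma_grid)
    logL = np.full(grid.size, np.nan)
    for k, gamma in enumerate(grid):
        try:
            G = build_grm(code_genotypes(X, gamma=gamma))
            _, logL[k] = fit_greml(G, pheno)
        except (ValueError, linalg.LinAlgError) as exc:
            warnings.warn(f"REML failed at gamma={gamma}: {exc}", stacklevel=2)
    return ScanResult(gamma_grid=grid, logL=logL)


def _gblup_predict(
    G: np.ndarray,
    train: np.ndarray,
    val: np.ndarray,
    pheno: PhenotypeSet,
    varcomp: VarianceComponents,
) -> tuple[float, np.ndarray]:
    """Training GLS mean and validation DGV from the cross-relationship block."""
    y_t, wt_t = pheno.y[train], pheno.weights[train]
    V_tt = varcomp.sigma_a2 * G[np.ix_(train, train)] + np.diag(
        varcomp.sigma_e2 / wt_t
    )
    cho = linalg.cho_factor(V_tt)
    ones = np.ones(train.size)
    mu_hat = float(ones @ linalg.cho_solve(cho, y_t)) / float(
        ones @ linalg.cho_solve(cho, ones)
    )
    g_val = varcomp.sigma_a2 * (
        G[np.ix_(val, train)] @ linalg.cho_solve(cho, y_t - mu_hat)
    )
    return mu_hat, g_val


def scan_msep(
    X: GenotypeMatrix,
    pheno: PhenotypeSet,
    spec: SplitSpec,
    gamma_grid=None,
    freqs_from: Literal["full", "train"] = "full",
) -> ScanResult:
    """Weighted MSEP on the validation set at each gamma.

    For every grid point the variance components and the general mean are
    estimated on the training individuals only; validation genomic values
    come from the train-validation relationship block.  Allele frequencies
    for the coding are taken from the full dataset by default
    (``freqs_from="train"`` restricts them to the training individuals).
    """
    grid = _prepare_grid(default_gamma_grid() if gamma_grid is None else gamma_grid)
    train, val = split(pheno, spec)
    if freqs_from == "full":
        p = allele_frequency(X)
    elif freqs_from == "train":
        p = allele_frequency(X.values[train, :])
    else:
        raise ValueError(f"unknown freqs_from: {freqs_from!r}")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError(
            "monomorphic loci under the chosen frequency source; filter first"
        )
    pheno_train = PhenotypeSet(
        y=pheno.y[train],
        weights=pheno.weights[train],
        ids=[pheno.ids[i] for i in train],
    )
    out = np.full(grid.size, np.nan)
    for k, gamma in enumerate(grid):
        try:
            G = build_grm(code_genotypes(X, gamma=gamma, freqs=p))
            varcomp, _ = fit_greml(G[np.ix_(train, train)], pheno_train)
            mu_hat, g_val = _gblup_predict(G, train, val, pheno, varcomp)
            out[k] = msep(mu_hat + g_val, pheno.y[val], pheno.weights[val])
        except (ValueError, linalg.LinAlgError) as exc:
            warnings.warn(f"MSEP scan failed at gamma={gamma}: {exc}", stacklevel=2)
    return ScanResult(gamma_grid=grid, msep=out)


class GammaScan(BaseEstimator):
    """Model selection over the allele-count scaling exponent.

    Fits the weighted SNP-BLUP model at every gamma on the grid and records
    the restricted log-likelihood (full data) and, when a split is
    requested, the weighted MSEP (validation individuals).

    Parameters
    ----------
    gamma_grid:
        Iterable of gamma values in [-1, 0]; default -1, -0.9, ..., 0.
    criterion:
        ``"loglik"``, ``"msep"`` or ``"both"``.
    train_fraction:
        Fraction of individuals (input order) used for training when the
        MSEP criterion runs.
    freqs_from:
        Frequency source for the MSEP coding, ``"full"`` or ``"train"``.

    Attributes
    ----------
    result_ : ScanResult
    best_gamma_loglik_ : float (when the likelihood criterion ran)
    best_gamma_msep_ : float (when the MSEP criterion ran)
    """

    def __init__(
        self,
        gamma_grid=None,
        criterion: Literal["loglik", "msep", "both"] = "loglik",
        train_fraction: float = 0.6,
        freqs_from: Literal["full", "train"] = "full",
    ) -> None:
        self.gamma_grid = gamma_grid
        self.criterion = criterion
        self.train_fraction = train_fraction
        self.freqs_from = freqs_from

    def fit(self, X, y, sample_weight=None):
        if not isinstance(X, GenotypeMatrix):
            X = GenotypeMatrix(np.asarray(X))
        pheno = PhenotypeSet(
            y=np.asarray(y, dtype=float),
            weights=sample_weight,
            ids=list(X.sample_ids),
        )
        if self.criterion not in ("loglik", "msep", "both"):
            raise ValueError(f"unknown criterion: {self.criterion!r}")
        grid = self.gamma_grid
        logL = mse = None
        if self.criterion in ("loglik", "both"):
            logL = scan_loglik(X, pheno, grid).logL
        if self.criterion in ("msep", "both"):
            spec = SplitSpec(rule="by_order", train_fraction=self.train_fraction)
            mse = scan_msep(X, pheno, spec, grid, freqs_from=self.freqs_from).msep
        self.result_ = ScanResult(
            gamma_grid=_prepare_grid(
                default_gamma_grid() if grid is None else grid
            ),
            logL=logL,
            msep=mse,
        )
        if logL is not None:
            self.best_gamma_loglik_ = self.result_.best_gamma_logL
        if mse is not None:
            self.best_gamma_msep_ = self.result_.best_gamma_msep
        return self
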