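"""Trait covariance, eigendecomposition and principal-component scores.

Every test in this package operates on the principal components of the trait
covariance matrix: the m traits are rotated into m uncorrelated scores ordered
by decreasing explained variance, and each score is tested against the variant
separately downstream.  PCA is done on the covariance (not correlation) matrix
and traits are column-centered before projection, so the score columns have
sample mean zero, pairwise sample covariance zero and sample variance equal to
the corresponding eigenvalue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TraitMatrix",
    "CovMatrix",
    "PCDecomposition",
    "compute_covariance",
    "eigendecompose",
    "project_scores",
    "pca",
]


class DegenerateInputError(ValueError):
    """Raised for inputs that do not support the computation (e.g. n < 3)."""


@dataclass
class TraitMatrix:
    """n x m quantitative phenotype observations, complete (no missing)."""

    values: np.ndarray
    sample_ids: Sequence[str] | None = None
    trait_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trait matrix must be two-dimensional")
        n, m = self.values.shape
        if n < 3:
            raise DegenerateInputError(f"need at least 3 samples, got {n}")
        if m < 2:
            raise DegenerateInputError(f"need at least 2 traits, got {m}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait matrix contains non-finite entries; "
                             "resolve missing values before analysis")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if self.trait_ids is None:
            self.trait_ids = [f"trait{j}" for j in range(m)]
        if len(self.sample_ids) != n or len(self.trait_ids) != m:
            raise ValueError("label lengths do not match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class CovMatrix:
    """Symmetric positive semi-definite m x m trait covariance."""

    delta: np.ndarray

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        m = self.delta.shape[0]
        if self.delta.shape != (m, m):
            raise ValueError("covariance matrix must be square")
        scale = max(np.abs(self.delta).max(), 1.0)
        if np.abs(self.delta - self.delta.T).max() > 1e-8 * scale:
            raise ValueError("covariance matrix is not symmetric")
        # symmetrize exactly so eigh sees a clean input
        self.delta = 0.5 * (self.delta + self.delta.T)

    @property
    def m(self) -> int:
        return self.delta.shape[0]


@dataclass
class PCDecomposition:
    """Eigenvalues (descending), eigenvector matrix Q and scores Z = Yc Q."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    scores: np.ndarray | None = None
    trait_means: np.ndarray | None = field(default=None)

    @property
    def m(self) -> int:
        return self.eigenvectors.shape[0]


def compute_covariance(traits: TraitMatrix) -> CovMatrix:
    """Sample covariance with the n-1 denominator.

    Entry (j1, j2) is sum_i (y_ij1 - mean_j1)(y_ij2 - mean_j2) / (n - 1).
    Constant trait columns are allowed (zero variance, eigenvalue 0) but
    trigger a warning because they carry no association signal.
    """
    y = traits.values
    variances = y.var(axis=0, ddof=1)
    if np.any(variances == 0):
        idx = [traits.trait_ids[j] for j in np.flatnonzero(variances == 0)]
        warnings.warn(f"constant trait column(s): {idx}; their eigenvalue "
                      "will be 0 and they contribute no evidence")
    return CovMatrix(np.cov(y, rowvar=False, ddof=1))


def eigendecompose(cov: CovMatrix) -> PCDecomposition:
    """Eigendecomposition Delta = Q Lambda Q^T with descending eigenvalues.

    Tiny negative eigenvalues from round-off (within 1e-8 of the eigenvalue
    scale) are clamped to zero; genuinely indefinite input raises.
    """
    lam, q = np.linalg.eigh(cov.delta)
    order = np.argsort(lam, kind="stable")[::-1]
    lam = lam[order]
    q = q[:, order]
    tol = 1e-8 * max(lam[0], np.trace(cov.delta) / cov.m, 1e-300)
    if lam[-1] < -tol:
        raise ValueError(
            f"covariance matrix is not positive semi-definite "
            f"(smallest eigenvalue {lam[-1]:.3e})")
    lam = np.clip(lam, 0.0, None)
    return PCDecomposition(eigenvalues=lam, eigenvectors=q)


def project_scores(traits: TraitMatrix, decomp: PCDecomposition) -> PCDecomposition:
    """Fill the score matrix Z = (Y - column means) Q."""
    if traits.m != decomp.m:
        raise ValueError(
            f"trait matrix has {traits.m} traits but decomposition is "
            f"{decomp.m}-dimensional")
    means = traits.values.mean(axis=0)
    decomp.scores = (traits.values - means) @ decomp.eigenvectors
    decomp.trait_means = means
    return decomp


def pca(traits: TraitMatrix) -> PCDecomposition:
    """Covariance PCA of a trait matrix: covariance, eigenpairs, scores."""
    return project_scores(traits, eigendecompose(compute_covariance(traits)))
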