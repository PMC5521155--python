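"""Per-PC Wald statistics for the genotype effect.

Each principal-component score column z_j is regressed on the additive
genotype dosage (plus an intercept and optional covariates) by ordinary least
squares, and T_j = beta_hat_j / se(beta_hat_j).  Under the null of no
association the T_j are asymptotically i.i.d. standard normal, which is what
the grouped combination tests downstream rely on.

The m regressions share one design matrix, so they are solved in a single
vectorized least-squares pass rather than one model fit per column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pca import PCDecomposition

__all__ = ["GenotypeVector", "WaldVector", "wald_statistics"]


class MonomorphicVariantError(ValueError):
    """The genotype vector is constant; no association test is possible."""


class CollinearityError(ValueError):
    """The regression design matrix is rank deficient."""


@dataclass
class GenotypeVector:
    """Additive-coded dosages (0..2) for one variant across n samples."""

    g: np.ndarray
    variant_id: str = "variant"

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 1:
            raise ValueError("genotype must be a vector")
        if np.ptp(self.g) == 0:
            raise MonomorphicVariantError(
                f"{self.variant_id}: genotype is constant")

    @property
    def n(self) -> int:
        return self.g.size

    @property
    def maf(self) -> float:
        """Allele frequency folded to the minor side (<= 0.5)."""
        freq = float(np.mean(self.g)) / 2.0
        return min(freq, 1.0 - freq)


@dataclass
class WaldVector:
    """T_1..T_m ordered by descending eigenvalue, plus residual dof."""

    t: np.ndarray
    dof_resid: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite Wald statistic")

    @property
    def m(self) -> int:
        return self.t.size


# |T| beyond this means a numerically perfect fit; the statistic is capped so
# downstream chi-square survival terms stay finite.
_T_CAP = 1e8


def wald_statistics(decomp: PCDecomposition,
                    geno: GenotypeVector,
                    covariates: np.ndarray | None = None) -> WaldVector:
    """OLS Wald statistics of each PC score on the genotype.

    Parameters
    ----------
    decomp
        PCA of the traits with scores filled (``project_scores``).
    geno
        Additive genotype dosages, length n.
    covariates
        Optional n x c matrix entering every per-PC regression.

    Returns
    -------
    WaldVector with t[j] = beta_hat_j / se_j, se from the residual variance
    with n - (c + 2) degrees of freedom.
    """
    z = decomp.scores
    if z is None:
        raise ValueError("decomposition has no scores; run project_scores")
    n = z.shape[0]
    if geno.n != n:
        raise ValueError("genotype length does not match trait matrix")

    g = geno.g
    if covariates is None:
        x = np.column_stack([np.ones(n), g])
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        x = np.column_stack([np.ones(n), covariates, g])

    p = x.shape[1]
    q, r = np.linalg.qr(x)
    if np.abs(np.diag(r)).min() <= 1e-10 * np.abs(np.diag(r)).max():
        raise CollinearityError("design matrix is rank deficient "
                                "(covariate collinear with genotype?)")
    dof = n - p
    if dof < 1:
        raise ValueError("not enough samples for the requested design")

    coef = np.linalg.solve(r, q.T @ z)          # p x m
    resid = z - x @ coef
    sigma2 = (resid ** 2).sum(axis=0) / dof
    # (X'X)^-1 last diagonal entry via R^-1
    rinv_last = np.linalg.solve(r.T, np.eye(p)[:, -1])
    var_g = float(rinv_last @ rinv_last)
    se = np.sqrt(sigma2 * var_g)

    t = np.zeros(z.shape[1])
    zero_var = decomp.eigenvalues <= 1e-12 * max(decomp.eigenvalues[0], 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        nonzero = se > 0
        t[nonzero] = coef[-1, nonzero] / se[nonzero]
    if np.any(~nonzero & ~zero_var):
        warnings.warn("perfect fit for a non-degenerate PC; Wald statistic "
                      f"capped at {_T_CAP:g}")
        t[~nonzero & ~zero_var] = np.sign(coef[-1, ~nonzero & ~zero_var]) * _T_CAP
    if np.any(zero_var):
        warnings.warn("zero-variance PC column(s); their Wald statistics are "
                      "set to 0 and contribute no evidence")
        t[zero_var] = 0.0
    np.clip(t, -_T_CAP, _T_CAP, out=t)
    return WaldVector(t=t, dof_resid=dof)
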