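"""Synthetic genotypes and correlated phenotypes from two latent-factor models.

Model 1 (indirect effects): the variant acts on latent factors, each latent
drives a block of four traits with a shared loading, so the trait correlation
matrix is block diagonal.  Model 2 (direct effects): one latent factor is
shared by all traits (giving a dense correlation matrix) and the variant acts
on each associated trait directly, independently of the latent.

Sixteen named structures fix the loadings:

* S1-S4   Model 1, m = 20 (uniform 0.5 / uniform 2.0 / gradients)
* S5-S8   Model 1, m = 100 (same four patterns, 25 latents)
* S9-S12  Model 2, m = 20
* S13-S16 Model 2, m = 100

All error terms are standard normal; genotypes are Hardy-Weinberg draws at a
given minor-allele frequency.  Per-trait effect sizes are solved in closed
form from the fraction of trait variance the variant should explain, so a
scenario is specified by (structure, MAF, n, fraction of traits associated,
per-trait explained variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pca import TraitMatrix
from .wald import GenotypeVector

__all__ = [
    "StructureSpec",
    "EffectConfig",
    "structure_spec",
    "analytic_correlation",
    "solve_beta_model1",
    "solve_beta_model2",
    "simulate_genotypes",
    "simulate_model1",
    "simulate_model2",
    "simulate_dataset",
    "STRUCTURES",
]

BLOCK_SIZE = 4  # traits per latent factor in Model 1


@dataclass
class StructureSpec:
    """Named latent-loading configuration defining a trait correlation."""

    name: str
    model: int            # 1 = indirect (block latents), 2 = direct (one latent)
    m: int
    gamma: np.ndarray     # per-latent loadings (Model 1) or per-trait (Model 2)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.model == 1:
            if self.m != BLOCK_SIZE * self.gamma.size:
                raise ValueError("Model 1 needs m = 4 * number of latents")
        elif self.model == 2:
            if self.m != self.gamma.size:
                raise ValueError("Model 2 needs one loading per trait")
        else:
            raise ValueError(f"unknown model {self.model}")

    @property
    def n_latents(self) -> int:
        return self.gamma.size if self.model == 1 else 1

    @property
    def trait_gamma(self) -> np.ndarray:
        """Loading of each trait on its latent (length m)."""
        if self.model == 1:
            return np.repeat(self.gamma, BLOCK_SIZE)
        return self.gamma


def _gradient(start: float, step: float, count: int) -> np.ndarray:
    return start - step * np.arange(count)


#: the named structures; uniform low/strong and moderate/strong gradients
STRUCTURES: dict[str, StructureSpec] = {
    # Model 1, m = 20 (5 latents)
    "S1": StructureSpec("S1", 1, 20, np.full(5, 0.5)),
    "S2": StructureSpec("S2", 1, 20, np.full(5, 2.0)),
    "S3": StructureSpec("S3", 1, 20, np.array([1.0, 0.8, 0.6, 0.4, 0.2])),
    "S4": StructureSpec("S4", 1, 20, np.array([1.5, 1.3, 1.1, 0.9, 0.7])),
    # Model 1, m = 100 (25 latents)
    "S5": StructureSpec("S5", 1, 100, np.full(25, 0.5)),
    "S6": StructureSpec("S6", 1, 100, np.full(25, 2.0)),
    "S7": StructureSpec("S7", 1, 100, _gradient(1.0, 0.04, 25)),
    "S8": StructureSpec("S8", 1, 100, _gradient(1.5, 0.04, 25)),
    # Model 2, m = 20
    "S9": StructureSpec("S9", 2, 20, np.full(20, 0.5)),
    "S10": StructureSpec("S10", 2, 20, np.full(20, 2.0)),
    "S11": StructureSpec("S11", 2, 20, _gradient(1.0, 0.05, 20)),
    "S12": StructureSpec("S12", 2, 20, _gradient(1.5, 0.05, 20)),
    # Model 2, m = 100 (same patterns scaled to 100 traits)
    "S13": StructureSpec("S13", 2, 100, np.full(100, 0.5)),
    "S14": StructureSpec("S14", 2, 100, np.full(100, 2.0)),
    "S15": StructureSpec("S15", 2, 100, _gradient(1.0, 0.01, 100)),
    "S16": StructureSpec("S16", 2, 100, _gradient(1.5, 0.01, 100)),
}


def structure_spec(name: str) -> StructureSpec:
    """Look up one of the named structures S1..S16."""
    try:
        return STRUCTURES[name]
    except KeyError:
        raise ValueError(f"unknown structure {name!r}; "
                         f"expected one of {sorted(STRUCTURES)}") from None


def analytic_correlation(spec: StructureSpec) -> np.ndarray:
    """Null trait correlation matrix implied by the loadings.

    corr(Y_i, Y_j) = g_i g_j / sqrt((1 + g_i^2)(1 + g_j^2)) for traits
    sharing a latent factor (within a block for Model 1, all pairs for
    Model 2), zero across Model 1 blocks, ones on the diagonal.
    """
    g = spec.trait_gamma
    scale = np.sqrt(1.0 + g ** 2)
    corr = np.outer(g, g) / np.outer(scale, scale)
    if spec.model == 1:
        block = np.repeat(np.arange(spec.n_latents), BLOCK_SIZE)
        corr = corr * (block[:, None] == block[None, :])
    np.fill_diagonal(corr, 1.0)
    return corr


def solve_beta_model1(h2: float, maf: float, gamma: float) -> float:
    """Per-latent effect so each trait in the block has explained variance h2.

    Inverts h2 = 2p(1-p) b^2 g^2 / (1 + g^2 + 2p(1-p) b^2 g^2).
    """
    if not 0 <= h2 < 1:
        raise ValueError("h2 must be in [0, 1)")
    if h2 == 0:
        return 0.0
    if gamma == 0:
        raise ValueError("a zero loading cannot transmit any effect (h2 > 0)")
    pq2 = 2.0 * maf * (1.0 - maf)
    return float(np.sqrt(h2 * (1.0 + gamma ** 2) /
                         (pq2 * gamma ** 2 * (1.0 - h2))))


def solve_beta_model2(h2: float, maf: float, gamma_row) -> float:
    """Per-trait direct effect for explained variance h2.

    Inverts h2 = 2p(1-p) b^2 / (sum(g^2) + 1 + 2p(1-p) b^2); ``gamma_row``
    is the trait's loadings on the latent factors (a scalar for one latent).
    """
    if not 0 <= h2 < 1:
        raise ValueError("h2 must be in [0, 1)")
    if h2 == 0:
        return 0.0
    gsq = float(np.sum(np.square(gamma_row)))
    pq2 = 2.0 * maf * (1.0 - maf)
    return float(np.sqrt(h2 * (gsq + 1.0) / (pq2 * (1.0 - h2))))


@dataclass
class EffectConfig:
    """Sample size, allele frequency and genetic-effect layout of a scenario."""

    maf: float
    n: int
    h2: float = 0.0            # per-associated-trait explained variance
    lambda_assoc: float = 0.0  # fraction of traits associated
    assignment: str = "first_k"  # or "random"

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not 0 <= self.h2 < 1:
            raise ValueError("h2 must be in [0, 1)")
        if not 0 <= self.lambda_assoc <= 1:
            raise ValueError("lambda_assoc must be in [0, 1]")
        if self.assignment not in ("first_k", "random"):
            raise ValueError("assignment must be 'first_k' or 'random'")


def default_sample_size(maf: float) -> int:
    """Sample-size convention of the simulation studies.

    1500 individuals for rare-to-moderate variants (MAF <= 0.15), 1000 for
    common ones, so the power of the compared tests falls in the same range
    across the MAF grid.
    """
    return 1500 if maf <= 0.15 else 1000


def simulate_genotypes(n: int, maf: float,
                       seed=None, rng: np.random.Generator | None = None
                       ) -> GenotypeVector:
    """i.i.d. Hardy-Weinberg genotypes: P(0,1,2) = ((1-p)^2, 2p(1-p), p^2).

    A monomorphic draw (possible at small n·p) is resampled.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if rng is None:
        rng = np.random.default_rng(seed)
    for attempt in range(1000):
        g = rng.binomial(2, maf, size=n).astype(float)
        if np.ptp(g) > 0:
            if attempt:
                import warnings
                warnings.warn(f"resampled {attempt} monomorphic draw(s)")
            return GenotypeVector(g, variant_id=f"sim_maf{maf:g}")
    raise RuntimeError("could not draw a polymorphic genotype")


def _active_traits(spec: StructureSpec, effect: EffectConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of associated traits under the chosen assignment.

    For Model 1 whole latent blocks are activated (a latent's effect reaches
    all four of its traits), so lambda * m must be block-aligned.
    """
    m = spec.m
    k = effect.lambda_assoc * m
    if abs(k - round(k)) > 1e-9:
        raise ValueError("lambda_assoc * m must be an integer")
    k = int(round(k))
    mask = np.zeros(m, dtype=bool)
    if spec.model == 1:
        if k % BLOCK_SIZE:
            raise ValueError(
                f"Model 1 associates whole latent blocks; lambda*m={k} is "
                f"not a multiple of {BLOCK_SIZE}")
        nblocks = k // BLOCK_SIZE
        if effect.assignment == "random":
            blocks = rng.choice(spec.n_latents, size=nblocks, replace=False)
        else:
            blocks = np.arange(nblocks)
        for b in blocks:
            mask[b * BLOCK_SIZE:(b + 1) * BLOCK_SIZE] = True
    else:
        if effect.assignment == "random":
            mask[rng.choice(m, size=k, replace=False)] = True
        else:
            mask[:k] = True
    return mask


def simulate_model1(spec: StructureSpec, effect: EffectConfig,
                    seed=None, rng: np.random.Generator | None = None
                    ) -> tuple[TraitMatrix, GenotypeVector]:
    """Indirect model: U_l = G b_l + e_l, Y_i = U_block(i) g_i + eps_i."""
    if spec.model != 1:
        raise ValueError(f"{spec.name} is not a Model 1 structure")
    if rng is None:
        rng = np.random.default_rng(seed)
    geno = simulate_genotypes(effect.n, effect.maf, rng=rng)
    mask = _active_traits(spec, effect, rng)
    active_latents = mask[::BLOCK_SIZE]
    beta = np.zeros(spec.n_latents)
    for latent in np.flatnonzero(active_latents):
        beta[latent] = solve_beta_model1(effect.h2, effect.maf,
                                         spec.gamma[latent])
    u = np.outer(geno.g, beta) + rng.standard_normal((effect.n, spec.n_latents))
    eps = rng.standard_normal((effect.n, spec.m))
    y = u[:, np.repeat(np.arange(spec.n_latents), BLOCK_SIZE)] \
        * spec.trait_gamma + eps
    return TraitMatrix(y), geno


def simulate_model2(spec: StructureSpec, effect: EffectConfig,
                    seed=None, rng: np.random.Generator | None = None
                    ) -> tuple[TraitMatrix, GenotypeVector]:
    """Direct model: Y_i = U g_i + G b_i + eps_i with one shared latent."""
    if spec.model != 2:
        raise ValueError(f"{spec.name} is not a Model 2 structure")
    if rng is None:
        rng = np.random.default_rng(seed)
    geno = simulate_genotypes(effect.n, effect.maf, rng=rng)
    mask = _active_traits(spec, effect, rng)
    beta = np.zeros(spec.m)
    for i in np.flatnonzero(mask):
        beta[i] = solve_beta_model2(effect.h2, effect.maf, spec.gamma[i])
    u = rng.standard_normal(effect.n)
    eps = rng.standard_normal((effect.n, spec.m))
    y = np.outer(u, spec.gamma) + np.outer(geno.g, beta) + eps
    return TraitMatrix(y), geno


def simulate_dataset(spec: StructureSpec, effect: EffectConfig,
                     seed=None, rng: np.random.Generator | None = None
                     ) -> tuple[TraitMatrix, GenotypeVector]:
    """Dispatch to the structure's model."""
    sim = simulate_model1 if spec.model == 1 else simulate_model2
    return sim(spec, effect, seed=seed, rng=rng)
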