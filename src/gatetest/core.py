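"""The GATE statistic and its one-layer resampling null distribution.

The m per-PC Wald statistics, ordered by descending eigenvalue, are split into
K consecutive groups.  For one grouping (m_1, ..., m_K) the grouped Fisher
combination is

    xi = sum_t  -2 * log( S_{m_t}( sum of T^2 in group t ) )

where S_d is the chi-square survival function with d degrees of freedom.  For
each K the grouping is chosen to maximize xi, the maximum is converted to an
empirical tail probability under a resampled standard-normal null, and GATE is
the minimum of those tail probabilities over K = 1..k_max.  Significance comes
from the same B resampled draw sets ("one-layer" reuse): each null draw is
pushed through the identical pipeline against the shared empirical CDFs, and
the p-value is the fraction of null GATE values at least as extreme as the
observed one.

The null depends only on (m, k_max, B, seed) — never on the genotype or the
traits — so one NullDistribution serves an entire genome scan.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import stats

from .wald import WaldVector

__all__ = [
    "Composition",
    "NullDistribution",
    "GateResult",
    "enumerate_compositions",
    "xi_statistic",
    "max_xi",
    "build_null",
    "gate_statistic",
    "gate_pvalue",
    "gate_test",
    "gate_pvalues_batch",
    "fit_ggd_null",
]

#: guard against combinatorial explosion when materializing composition lists
MAX_COMPOSITIONS = 10 ** 6


Composition = tuple[int, ...]


def enumerate_compositions(m: int, K: int, force: bool = False) -> list[Composition]:
    """All ordered compositions of m into K positive parts, lexicographic.

    There are C(m-1, K-1) of them; requests above ``MAX_COMPOSITIONS`` raise
    unless ``force`` is set.
    """
    if not 1 <= K <= m:
        raise ValueError(f"need 1 <= K <= m, got K={K}, m={m}")
    count = math.comb(m - 1, K - 1)
    if count > MAX_COMPOSITIONS and not force:
        raise ValueError(
            f"{count} compositions of {m} into {K} parts exceeds the "
            f"{MAX_COMPOSITIONS} guard; pass force=True to override")
    out = []
    for cuts in combinations(range(1, m), K - 1):
        bounds = (0,) + cuts + (m,)
        out.append(tuple(bounds[i + 1] - bounds[i] for i in range(K)))
    return out


def _as_t(wald) -> np.ndarray:
    if isinstance(wald, WaldVector):
        return wald.t
    return np.asarray(wald, dtype=float)


def _group_terms(chi2sums: np.ndarray, dofs) -> np.ndarray:
    """-2 log S_d(x) elementwise, via the chi-square log-survival function."""
    return -2.0 * stats.chi2.logsf(chi2sums, dofs)


def xi_statistic(wald, comp: Composition) -> float:
    """Grouped Fisher combination for one fixed composition."""
    t = _as_t(wald)
    comp = tuple(int(c) for c in comp)
    if any(c <= 0 for c in comp) or sum(comp) != t.size:
        raise ValueError(f"composition {comp} does not partition m={t.size}")
    bounds = np.concatenate([[0], np.cumsum(comp)])
    t2 = t ** 2
    cs = np.concatenate([[0.0], np.cumsum(t2)])
    sums = cs[bounds[1:]] - cs[bounds[:-1]]
    return float(_group_terms(sums, np.asarray(comp)).sum())


def _max_xi_batch(t2: np.ndarray, K: int) -> np.ndarray:
    """Maximum xi over all K-part compositions, for a batch of T^2 rows.

    K = 1 and K = 2 (the recommended default) are fully vectorized; larger K
    uses a dynamic program over group boundaries, O(K m^2) per draw, which
    sidesteps enumerating the C(m-1, K-1) compositions.
    """
    b, m = t2.shape
    cs = np.concatenate([np.zeros((b, 1)), np.cumsum(t2, axis=1)], axis=1)
    total = cs[:, -1]
    if K == 1:
        return _group_terms(total, m)
    if K == 2:
        s = np.arange(1, m)
        left = _group_terms(cs[:, 1:m], s)
        right = _group_terms(total[:, None] - cs[:, 1:m], m - s)
        return (left + right).max(axis=1)
    # DP: best[j] = max xi over compositions of the first j statistics into
    # k groups; term(i, j) combines statistics i+1..j as one group.
    chunk = max(1, int(2e7 // (m * m)))
    out = np.empty(b)
    for lo in range(0, b, chunk):
        c = cs[lo:lo + chunk]
        nb = c.shape[0]
        term = np.full((m + 1, m + 1, nb), -np.inf)
        for i in range(m):
            sizes = np.arange(1, m - i + 1)          # group sizes j - i
            term[i, i + 1:] = _group_terms((c[:, i + 1:] - c[:, i:i + 1]).T,
                                           sizes[:, None])
        best = term[0].copy()                      # k = 1
        for _ in range(K - 1):
            nxt = np.full((m + 1, nb), -np.inf)
            for j in range(2, m + 1):
                cand = best[1:j] + term[1:j, j]
                nxt[j] = cand.max(axis=0)
            best = nxt
        out[lo:lo + chunk] = best[m]
    return out


def max_xi(wald, K: int) -> tuple[float, Composition]:
    """Maximum xi over all K-part compositions and an arg-max composition.

    Ties resolve to the first composition in lexicographic order.  Uses a
    dynamic program with backpointers, so large m with moderate K is fine.
    """
    t = _as_t(wald)
    m = t.size
    if not 1 <= K <= max(m - 1, 1):
        raise ValueError(f"need 1 <= K <= m-1, got K={K}, m={m}")
    cs = np.concatenate([[0.0], np.cumsum(t ** 2)])
    term = np.full((m + 1, m + 1), -np.inf)
    for i in range(m):
        sizes = np.arange(1, m - i + 1)              # group sizes j - i
        term[i, i + 1:] = _group_terms(cs[i + 1:] - cs[i], sizes)
    # best[k][j], backpointer to the previous boundary
    best = term[0].copy()
    back = [np.zeros(m + 1, dtype=int)]
    for _ in range(K - 1):
        nxt = np.full(m + 1, -np.inf)
        ptr = np.zeros(m + 1, dtype=int)
        for j in range(2, m + 1):
            cand = best[1:j] + term[1:j, j]
            # argmax returns the first maximizer -> lexicographically smallest
            # boundary, matching the enumeration order tie-break
            i = int(np.argmax(cand)) + 1
            nxt[j] = cand[i - 1]
            ptr[j] = i
        best, back = nxt, back + [ptr]
    bounds = [m]
    for k in range(K - 1, 0, -1):
        bounds.append(int(back[k][bounds[-1]]))
    bounds.append(0)
    bounds = bounds[::-1]
    comp = tuple(bounds[i + 1] - bounds[i] for i in range(K))
    return float(best[m]), comp


@dataclass
class NullDistribution:
    """Resampled null for GATE at fixed (m, k_max, B, seed).

    ``maxxi_draws[b, K-1]`` is the max-xi value of draw b for K groups;
    ``hk_ecdfs[K-1]`` is the same column sorted ascending (the empirical CDF
    H_K); ``eta_draws[b]`` is the null GATE value of draw b evaluated against
    those shared ECDFs (one-layer reuse, draw b included in its own ECDF).
    """

    m: int
    k_max: int
    B: int
    seed: int
    maxxi_draws: np.ndarray = field(repr=False)
    hk_ecdfs: list = field(repr=False)
    eta_draws: np.ndarray = field(repr=False)

    def tail(self, K: int, x) -> np.ndarray | float:
        """1 - H_K(x) evaluated as #{draws > x} / B (resolution 1/B)."""
        sorted_k = self.hk_ecdfs[K - 1]
        idx = np.searchsorted(sorted_k, x, side="right")
        return (self.B - idx) / self.B

    def save(self, path) -> None:
        np.savez_compressed(
            path, m=self.m, k_max=self.k_max, B=self.B, seed=self.seed,
            maxxi_draws=self.maxxi_draws, eta_draws=self.eta_draws)

    @classmethod
    def load(cls, path) -> "NullDistribution":
        with np.load(path) as z:
            maxxi = z["maxxi_draws"]
            return cls(m=int(z["m"]), k_max=int(z["k_max"]), B=int(z["B"]),
                       seed=int(z["seed"]), maxxi_draws=maxxi,
                       hk_ecdfs=[np.sort(maxxi[:, k]) for k in range(maxxi.shape[1])],
                       eta_draws=z["eta_draws"])

    @classmethod
    def cached(cls, m: int, k_max: int, B: int, seed: int,
               cache_dir=None) -> "NullDistribution":
        """Build, or load from ``cache_dir`` if a matching file exists."""
        if cache_dir is None:
            return build_null(m, k_max, B, seed)
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        path = cache_dir / f"gate_null_m{m}_k{k_max}_B{B}_s{seed}.npz"
        if path.exists():
            null = cls.load(path)
            if (null.m, null.k_max, null.B, null.seed) == (m, k_max, B, seed):
                return null
        null = build_null(m, k_max, B, seed)
        null.save(path)
        return null


def build_null(m: int, k_max: int, B: int, seed: int | None = None,
               rng: np.random.Generator | None = None) -> NullDistribution:
    """Resample B i.i.d. standard-normal T-vectors and build the GATE null.

    Reproducible bit-for-bit from (m, k_max, B, seed).  B >= 1000 enforced:
    below that the 1/B p-value resolution is useless in practice.
    """
    if B < 1000:
        raise ValueError("B must be at least 1000")
    if not 1 <= k_max <= max(m - 1, 1):
        raise ValueError(f"need 1 <= k_max <= m-1, got k_max={k_max}, m={m}")
    if rng is None:
        if seed is None:
            raise ValueError("provide a seed (or an explicit Generator)")
        rng = np.random.default_rng(seed)
    t2 = rng.standard_normal((B, m)) ** 2
    maxxi = np.column_stack([_max_xi_batch(t2, K) for K in range(1, k_max + 1)])
    ecdfs = [np.sort(maxxi[:, k]) for k in range(k_max)]
    tails = np.column_stack([
        (B - np.searchsorted(ecdfs[k], maxxi[:, k], side="right")) / B
        for k in range(k_max)])
    eta = tails.min(axis=1)
    return NullDistribution(m=m, k_max=k_max, B=B,
                            seed=-1 if seed is None else seed,
                            maxxi_draws=maxxi, hk_ecdfs=ecdfs, eta_draws=eta)


@dataclass
class GateResult:
    """Observed GATE statistic eta0 with per-K detail and its p-value."""

    eta0: float
    per_k: dict
    B: int
    k_max: int
    p_value: float | None = None
    p_value_is_zero_floor: bool = False

    def formatted_p(self) -> str:
        if self.p_value is None:
            return "NA"
        if self.p_value == 0.0:
            return f"< {1.0 / self.B:g}"
        return f"{self.p_value:g}"


def gate_statistic(wald, null: NullDistribution) -> GateResult:
    """Observed GATE: min over K of the empirical tail of the max-xi value."""
    t = _as_t(wald)
    if t.size != null.m:
        raise ValueError(
            f"Wald vector has m={t.size} but null was built for m={null.m}")
    per_k = {}
    eta0 = np.inf
    for K in range(1, null.k_max + 1):
        value, comp = max_xi(t, K)
        tail = float(null.tail(K, value))
        per_k[K] = {"composition": comp, "xi": value, "tail": tail}
        eta0 = min(eta0, tail)
    return GateResult(eta0=float(eta0), per_k=per_k, B=null.B,
                      k_max=null.k_max)


def gate_pvalue(result: GateResult, null: NullDistribution,
                paper_formula: bool = False,
                add_one_correction: bool = False) -> float:
    """Resampling p-value of the observed GATE statistic.

    Small eta means strong evidence, so the default counts null draws with
    eta <= eta0 (ties included).  ``paper_formula`` switches to the literal
    opposite-direction count #{eta(b) > eta0}/B for audit.  With
    ``add_one_correction`` the (r+1)/(B+1) permutation correction is applied,
    avoiding exact zeros.
    """
    if result.B != null.B or result.k_max != null.k_max:
        raise ValueError("result was not computed against this null")
    if paper_formula:
        p = float(np.count_nonzero(null.eta_draws > result.eta0)) / null.B
    else:
        r = int(np.count_nonzero(null.eta_draws <= result.eta0))
        if add_one_correction:
            p = (r + 1) / (null.B + 1)
        else:
            p = r / null.B
            result.p_value_is_zero_floor = p == 0.0
    result.p_value = p
    return p


def gate_test(traits, geno, covariates=None, null: NullDistribution | None = None,
              k_max: int = 2, B: int = 10000, seed: int = 0,
              paper_formula: bool = False) -> GateResult:
    """Convenience wrapper: PCA -> Wald vector -> GATE p-value.

    ``traits`` may be a TraitMatrix or a plain n x m array.  Pass a prebuilt
    ``null`` when scanning many variants so the resampling is done once.
    """
    from .pca import TraitMatrix, pca
    from .wald import GenotypeVector, wald_statistics

    if not isinstance(traits, TraitMatrix):
        traits = TraitMatrix(np.asarray(traits, dtype=float))
    if not isinstance(geno, GenotypeVector):
        geno = GenotypeVector(np.asarray(geno, dtype=float))
    decomp = pca(traits)
    wald = wald_statistics(decomp, geno, covariates)
    if null is None:
        null = build_null(traits.m, k_max, B, seed)
    result = gate_statistic(wald, null)
    gate_pvalue(result, null, paper_formula=paper_formula)
    return result


def gate_pvalues_batch(t_matrix: np.ndarray, null: NullDistribution,
                       paper_formula: bool = False) -> np.ndarray:
    """GATE p-values for many Wald vectors at once (rows of ``t_matrix``).

    Used by the simulation driver and genome scans; identical to calling
    gate_statistic/gate_pvalue row by row, just vectorized.
    """
    t2 = np.asarray(t_matrix, dtype=float) ** 2
    if t2.shape[1] != null.m:
        raise ValueError("Wald matrix width does not match null.m")
    tails = np.column_stack([
        null.tail(K, _max_xi_batch(t2, K)) for K in range(1, null.k_max + 1)])
    eta0 = tails.min(axis=1)
    sorted_eta = np.sort(null.eta_draws)
    if paper_formula:
        return (null.B - np.searchsorted(sorted_eta, eta0, side="right")) / null.B
    return np.searchsorted(sorted_eta, eta0, side="right") / null.B


@dataclass
class GGDFit:
    """Generalized-Gamma approximation to the null of -2 ln(GATE)."""

    a: float
    c: float
    loc: float
    scale: float

    def quantile(self, q):
        return stats.gengamma.ppf(q, self.a, self.c,
                                  loc=self.loc, scale=self.scale)

    def pvalue(self, eta0: float, floor: float) -> float:
        """Approximate p-value from the fitted tail of -2 ln(eta)."""
        x = -2.0 * math.log(max(eta0, floor))
        return float(stats.gengamma.sf(x, self.a, self.c,
                                       loc=self.loc, scale=self.scale))


def fit_ggd_null(null: NullDistribution) -> GGDFit:
    """Maximum-likelihood generalized-Gamma fit to the -2 ln(eta) null draws.

    Exact zeros of eta (draws beyond every other draw) are replaced by the
    continuity offset 1/(2B) before taking logs.  Intended for large B
    (>= 1e5) where the far tail needs smoothing beyond the 1/B resolution.
    """
    eta = np.maximum(null.eta_draws, 1.0 / (2 * null.B))
    x = -2.0 * np.log(eta)
    if np.ptp(x) == 0:
        raise RuntimeError("degenerate null draws (all equal); cannot fit")
    if null.B < 10 ** 5:
        warnings.warn("generalized-Gamma fit is recommended for B >= 1e5; "
                      f"got B={null.B}")
    try:
        a, c, loc, scale = stats.gengamma.fit(x, floc=0.0)
    except Exception as exc:  # scipy raises various optimizer errors
        raise RuntimeError(f"generalized-Gamma fit failed: {exc}") from exc
    if not np.all(np.isfinite([a, c, loc, scale])) or scale <= 0:
        raise RuntimeError(
            f"generalized-Gamma fit did not converge: a={a}, c={c}, "
            f"loc={loc}, scale={scale}")
    return GGDFit(a=float(a), c=float(c), loc=float(loc), scale=float(scale))
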