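"""Pairwise linkage disequilibrium and haplotype-block calling.

Implements the two-locus LD statistics r² and D′ from phased haplotype
panels, a likelihood-grid confidence interval for |D′|, an EM estimator of
two-locus haplotype frequencies for unphased genotype tables, a windowed
pairwise LD scan with MAF and r² storage floors, and Gabriel-style
haplotype-block calling from the D′ confidence intervals.

Coordinate conventions: SNP positions are 1-based point coordinates;
LDBlock start/end are 1-based and inclusive of the outermost SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypePanel",
    "TwoLocusCounts",
    "LDPairTable",
    "LDBlock",
    "two_locus_counts",
    "r2_dprime",
    "em_haplotype_freqs",
    "dprime_ci",
    "pairwise_ld_scan",
    "call_ld_blocks",
]


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix over bi-allelic SNPs on one chromosome.

    ``alleles`` is a (n_haplotypes, n_snps) matrix of {0, 1}; haplotypes
    2k and 2k+1 belong to sample k. ``positions`` are 1-based and strictly
    increasing. ``sample_population`` holds one label per sample.
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom: str = "chr1"
    sample_population: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype x SNP matrix")
        if self.alleles.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even (two per sample)")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length must match SNP count")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("SNP positions must be strictly increasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be 0/1")
        if self.sample_population is None:
            self.sample_population = np.full(self.n_samples, "ALL", dtype=object)
        else:
            self.sample_population = np.asarray(self.sample_population, dtype=object)
            if self.sample_population.shape[0] != self.n_samples:
                raise ValueError("one population label per sample required")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def maf(self) -> np.ndarray:
        freq = self.alleles.mean(axis=0)
        return np.minimum(freq, 1.0 - freq)

    def filter_maf(self, maf_min: float) -> "HaplotypePanel":
        """Return a panel restricted to SNPs with MAF >= ``maf_min``."""
        keep = self.maf >= maf_min
        return HaplotypePanel(
            self.alleles[:, keep],
            self.positions[keep],
            chrom=self.chrom,
            sample_population=self.sample_population,
        )

    def subset_population(self, population: str) -> "HaplotypePanel":
        mask = self.sample_population == population
        hap_mask = np.repeat(mask, 2)
        return HaplotypePanel(
            self.alleles[hap_mask],
            self.positions,
            chrom=self.chrom,
            sample_population=self.sample_population[mask],
        )


@dataclass(frozen=True)
class TwoLocusCounts:
    """Haplotype counts for alleles (A/a, B/b) at two loci; A = allele 1."""

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int

    @property
    def total(self) -> int:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab

    @property
    def p_A(self) -> float:
        return (self.n_AB + self.n_Ab) / self.total

    @property
    def p_B(self) -> float:
        return (self.n_AB + self.n_aB) / self.total


@dataclass
class LDPairTable:
    """Stored pairwise LD records; pairs below the storage floor are
    semantically r² = 0 downstream."""

    df: pd.DataFrame  # columns pos_i, pos_j, r2, dprime, distance
    population: str | None = None
    r2_floor: float = 0.01
    max_dist: int = 2_000_000

    def __post_init__(self) -> None:
        expected = {"pos_i", "pos_j", "r2", "dprime", "distance"}
        missing = expected - set(self.df.columns)
        if missing:
            raise ValueError(f"LDPairTable missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class LDBlock:
    """Called haplotype block; start/end 1-based inclusive of edge SNPs."""

    chrom: str
    start: int
    end: int
    snp_count: int
    population: str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def two_locus_counts(panel: HaplotypePanel, i: int, j: int) -> TwoLocusCounts:
    """Tally the four two-locus haplotype classes between SNPs ``i``, ``j``."""
    if i == j:
        raise ValueError("two distinct loci required")
    n = panel.n_snps
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError("SNP index out of range")
    a = panel.alleles[:, i].astype(bool)
    b = panel.alleles[:, j].astype(bool)
    return TwoLocusCounts(
        n_AB=int(np.sum(a & b)),
        n_Ab=int(np.sum(a & ~b)),
        n_aB=int(np.sum(~a & b)),
        n_ab=int(np.sum(~a & ~b)),
    )


def r2_dprime(counts: TwoLocusCounts) -> tuple[float, float]:
    """Definitional r² and D′ from four haplotype counts.

    D = p_AB − p_A·p_B; r² = D²/(p_A(1−p_A)p_B(1−p_B)); D′ = |D|/D_max with
    D_max depending on the sign of D. Both results are clipped to [0, 1]
    against floating-point rounding.
    """
    n = counts.total
    if n <= 0:
        raise ValueError("empty counts")
    p_AB = counts.n_AB / n
    p_A = counts.p_A
    p_B = counts.p_B
    if not (0.0 < p_A < 1.0) or not (0.0 < p_B < 1.0):
        raise ValueError("monomorphic locus: filter by MAF before computing LD")
    D = p_AB - p_A * p_B
    r2 = D * D / (p_A * (1 - p_A) * p_B * (1 - p_B))
    if D > 0:
        d_max = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    else:
        d_max = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    dprime = 0.0 if d_max == 0 else abs(D) / d_max
    return float(np.clip(r2, 0.0, 1.0)), float(np.clip(dprime, 0.0, 1.0))


def em_haplotype_freqs(
    genotype_table: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, int]:
    """EM estimate of two-locus haplotype frequencies from unphased data.

    ``genotype_table`` is a 3x3 count matrix indexed by copies of allele A
    (rows) and allele B (columns). Only double heterozygotes (cell [1,1])
    are phase-ambiguous: the E-step splits them between AB/ab and Ab/aB in
    proportion to p_AB·p_ab versus p_Ab·p_aB.

    Returns (frequencies [p_AB, p_Ab, p_aB, p_ab], iterations).
    Raises RuntimeError (carrying the last estimate) on non-convergence.
    """
    g = np.asarray(genotype_table, dtype=float)
    if g.shape != (3, 3) or g.sum() <= 0:
        raise ValueError("genotype_table must be a 3x3 count matrix with total > 0")
    n_hap = 2.0 * g.sum()
    # Unambiguous haplotype contributions from the eight phase-known cells.
    base = np.zeros(4)  # AB, Ab, aB, ab
    base[0] = 2 * g[2, 2] + g[2, 1] + g[1, 2]
    base[1] = 2 * g[2, 0] + g[2, 1] + g[1, 0]
    base[2] = 2 * g[0, 2] + g[0, 1] + g[1, 2]
    base[3] = 2 * g[0, 0] + g[0, 1] + g[1, 0]
    dh = g[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    p = np.full(4, 0.25)
    it = 0
    if dh == 0:
        p = base / base.sum()
        return p, 1
    for it in range(1, max_iter + 1):
        w_coupling = p[0] * p[3]
        w_repulsion = p[1] * p[2]
        tot = w_coupling + w_repulsion
        frac = 0.5 if tot == 0 else w_coupling / tot
        new = base.copy()
        new[[0, 3]] += dh * frac
        new[[1, 2]] += dh * (1.0 - frac)
        new /= n_hap
        if np.max(np.abs(new - p)) < tol:
            return new, it
        p = new
    err = RuntimeError(f"EM did not converge in {max_iter} iterations")
    err.last_estimate = p  # type: ignore[attr-defined]
    raise err


def _dprime_grid_loglik(
    n: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood of count rows ``n`` (shape (k,4): AB,Ab,aB,ab) at each
    |D′| grid value, allele frequencies fixed at their MLEs and the sign of
    D fixed at its point estimate. Returns (loglik (k,G), dprime grid)."""
    n = np.asarray(n, dtype=float)
    tot = n.sum(axis=1, keepdims=True)
    p_A = (n[:, [0]] + n[:, [1]]) / tot
    p_B = (n[:, [0]] + n[:, [2]]) / tot
    d_hat = n[:, [0]] / tot - p_A * p_B
    sign = np.where(d_hat >= 0, 1.0, -1.0)
    d_max = np.where(
        sign > 0,
        np.minimum(p_A * (1 - p_B), (1 - p_A) * p_B),
        np.minimum(p_A * p_B, (1 - p_A) * (1 - p_B)),
    )
    d = sign * d_max * grid[None, :]  # (k, G)
    bases = (p_A * p_B, p_A * (1 - p_B), (1 - p_A) * p_B,
             (1 - p_A) * (1 - p_B))
    signs = (1.0, -1.0, -1.0, 1.0)
    loglik = np.zeros((n.shape[0], grid.size))
    for cell, (base, s) in enumerate(zip(bases, signs)):
        p = np.clip(base + s * d, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = n[:, cell, None] * np.log(p)
        # 0 * log(0) -> nan; a zero count contributes nothing
        np.nan_to_num(term, copy=False, nan=0.0,
                      posinf=np.inf, neginf=-np.inf)
        loglik += term
    return loglik, grid


def _ci_from_loglik(loglik: np.ndarray, grid: np.ndarray, tail_mass: float):
    """Normalized-likelihood CI bounds per row of ``loglik``."""
    ll = loglik - loglik.max(axis=1, keepdims=True)
    w = np.exp(ll)
    w /= w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    # smallest grid value with cumulative mass >= tail_mass
    lo_idx = np.argmax(cum >= tail_mass, axis=1)
    # largest grid value whose upper-tail mass (from it to 1) >= tail_mass
    upper = 1.0 - cum + w
    hi_idx = w.shape[1] - 1 - np.argmax(upper[:, ::-1] >= tail_mass, axis=1)
    return grid[lo_idx], grid[hi_idx]


def dprime_ci(
    counts: TwoLocusCounts,
    grid_step: float = 0.001,
    tail_mass: float = 0.05,
) -> tuple[float, float]:
    """Likelihood-grid confidence interval for |D′| (Haploview-style).

    With allele frequencies fixed at their MLEs, evaluates the multinomial
    likelihood of the counts on a |D′| grid over [0, 1] (sign of D fixed at
    its point estimate), normalizes to unit mass, and reads off the
    ``tail_mass`` lower and upper bounds.
    """
    if not (0.0 < counts.p_A < 1.0) or not (0.0 < counts.p_B < 1.0):
        raise ValueError("monomorphic locus: CI undefined")
    grid = np.arange(0.0, 1.0 + 0.5 * grid_step, grid_step)
    grid = np.clip(grid, 0.0, 1.0)
    n = np.array([[counts.n_AB, counts.n_Ab, counts.n_aB, counts.n_ab]])
    ll, grid = _dprime_grid_loglik(n, grid)
    lo, hi = _ci_from_loglik(ll, grid, tail_mass)
    return float(lo[0]), float(hi[0])


def _pairwise_ld_matrices(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs r² and D′ matrices for a 0/1 haplotype matrix X (n x m)."""
    n = X.shape[0]
    Xf = X.astype(np.float64)
    p = Xf.mean(axis=0)
    p_ab = (Xf.T @ Xf) / n
    D = p_ab - np.outer(p, p)
    var = p * (1.0 - p)
    denom = np.outer(var, var)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, D * D / denom, np.nan)
    pos_max = np.minimum(np.outer(p, 1.0 - p), np.outer(1.0 - p, p))
    neg_max = np.minimum(np.outer(p, p), np.outer(1.0 - p, 1.0 - p))
    d_max = np.where(D > 0, pos_max, neg_max)
    with np.errstate(divide="ignore", invalid="ignore"):
        dprime = np.where(d_max > 0, np.abs(D) / d_max, np.nan)
    return np.clip(r2, 0.0, 1.0), np.clip(dprime, 0.0, 1.0)


def pairwise_ld_scan(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    max_dist: int = 2_000_000,
    r2_floor: float = 0.01,
    population: str | None = None,
) -> LDPairTable:
    """Windowed pairwise LD scan.

    Computes r² and D′ for every ordered SNP pair within ``max_dist`` among
    SNPs passing the MAF filter; records with r² below ``r2_floor`` are
    omitted from storage and treated as 0 downstream. When ``population``
    is given, only that population's haplotypes are used.
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    sub = panel.subset_population(population) if population is not None else panel
    sub = sub.filter_maf(maf_min)
    m = sub.n_snps
    if m < 2:
        df = pd.DataFrame(columns=["pos_i", "pos_j", "r2", "dprime", "distance"])
        return LDPairTable(df, population=population, r2_floor=r2_floor, max_dist=max_dist)
    r2, dprime = _pairwise_ld_matrices(sub.alleles)
    iu, ju = np.triu_indices(m, k=1)
    dist = sub.positions[ju] - sub.positions[iu]
    keep = (dist <= max_dist) & (r2[iu, ju] >= r2_floor)
    df = pd.DataFrame(
        {
            "pos_i": sub.positions[iu[keep]],
            "pos_j": sub.positions[ju[keep]],
            "r2": r2[iu[keep], ju[keep]],
            "dprime": dprime[iu[keep], ju[keep]],
            "distance": dist[keep],
        }
    )
    return LDPairTable(df, population=population, r2_floor=r2_floor, max_dist=max_dist)


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _ci_bounds_batch_py(counts: np.ndarray, grid: np.ndarray,
                        tail_mass: float) -> tuple[np.ndarray, np.ndarray]:
    k = counts.shape[0]
    G = grid.size
    lo = np.empty(k)
    hi = np.empty(k)
    w = np.empty(G)
    for p in range(k):
        nAB = counts[p, 0]
        nAb = counts[p, 1]
        naB = counts[p, 2]
        nab = counts[p, 3]
        tot = nAB + nAb + naB + nab
        pA = (nAB + nAb) / tot
        pB = (nAB + naB) / tot
        dhat = nAB / tot - pA * pB
        if dhat >= 0:
            dmax = min(pA * (1 - pB), (1 - pA) * pB)
            sign = 1.0
        else:
            dmax = min(pA * pB, (1 - pA) * (1 - pB))
            sign = -1.0
        mx = -np.inf
        for g in range(G):
            d = sign * dmax * grid[g]
            p1 = pA * pB + d
            p2 = pA * (1 - pB) - d
            p3 = (1 - pA) * pB - d
            p4 = (1 - pA) * (1 - pB) + d
            ll = 0.0
            bad = ((nAB > 0 and p1 <= 0.0) or (nAb > 0 and p2 <= 0.0)
                   or (naB > 0 and p3 <= 0.0) or (nab > 0 and p4 <= 0.0))
            if bad:
                ll = -np.inf
            else:
                if nAB > 0:
                    ll += nAB * np.log(p1)
                if nAb > 0:
                    ll += nAb * np.log(p2)
                if naB > 0:
                    ll += naB * np.log(p3)
                if nab > 0:
                    ll += nab * np.log(p4)
            w[g] = ll
            if ll > mx:
                mx = ll
        total = 0.0
        for g in range(G):
            w[g] = np.exp(w[g] - mx)
            total += w[g]
        target = tail_mass * total
        cum = 0.0
        lo_idx = G - 1
        for g in range(G):
            cum += w[g]
            if cum >= target:
                lo_idx = g
                break
        cum = 0.0
        hi_idx = 0
        for g in range(G - 1, -1, -1):
            cum += w[g]
            if cum >= target:
                hi_idx = g
                break
        lo[p] = grid[lo_idx]
        hi[p] = grid[hi_idx]
    return lo, hi


if _njit is not None:
    _ci_bounds_batch = _njit(cache=True)(_ci_bounds_batch_py)
else:  # pragma: no cover
    _ci_bounds_batch = _ci_bounds_batch_py


def _classify_pairs(
    X: np.ndarray,
    positions: np.ndarray,
    max_span: int,
    strong_low: float,
    strong_high: float,
    recomb_high: float,
    grid_step: float,
    tail_mass: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (m, m) matrices (strong LD, strong recombination) over the
    upper triangle of SNP pairs within ``max_span``."""
    n, m = X.shape
    Xf = X.astype(np.float64)
    n_ab = (Xf.T @ Xf)  # counts of AB per pair
    col = Xf.sum(axis=0)
    iu, ju = np.triu_indices(m, k=1)
    within = (positions[ju] - positions[iu]) <= max_span
    iu, ju = iu[within], ju[within]
    counts = np.empty((iu.size, 4))
    counts[:, 0] = n_ab[iu, ju]
    counts[:, 1] = col[iu] - counts[:, 0]
    counts[:, 2] = col[ju] - counts[:, 0]
    counts[:, 3] = n - counts[:, 0] - counts[:, 1] - counts[:, 2]
    grid = np.clip(np.arange(0.0, 1.0 + 0.5 * grid_step, grid_step), 0.0, 1.0)
    lo, hi = _ci_bounds_batch(counts, grid, tail_mass)
    strong = np.zeros((m, m), dtype=bool)
    recomb = np.zeros((m, m), dtype=bool)
    strong[iu, ju] = (lo >= strong_low) & (hi >= strong_high)
    recomb[iu, ju] = hi < recomb_high
    return strong, recomb


def call_ld_blocks(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    inform_frac: float = 0.95,
    max_span: int = 2_000_000,
    grid_step: float = 0.001,
    tail_mass: float = 0.05,
    population: str | None = None,
) -> list[LDBlock]:
    """Gabriel-style haplotype-block calling from D′ confidence intervals.

    Each SNP pair within ``max_span`` is classified by its |D′| CI: strong
    LD if ci_low >= strong_low and ci_high >= strong_high; strong
    recombination ("historical recombination") if ci_high < recomb_high;
    otherwise uninformative. A candidate block (i..j) requires the
    outermost pair to be strong LD and the strong fraction of informative
    pairs inside the block to reach ``inform_frac``. Candidates are
    accepted greedily by bp span descending (ties: leftmost start),
    skipping overlaps. Small-block span caps are disabled.
    """
    sub = panel.subset_population(population) if population is not None else panel
    sub = sub.filter_maf(maf_min)
    m = sub.n_snps
    if m < 2:
        return []
    strong, recomb = _classify_pairs(
        sub.alleles, sub.positions, max_span,
        strong_low, strong_high, recomb_high, grid_step, tail_mass,
    )
    # 2-D prefix sums for submatrix pair counts
    cs = np.zeros((m + 1, m + 1))
    cr = np.zeros((m + 1, m + 1))
    cs[1:, 1:] = np.cumsum(np.cumsum(strong, axis=0), axis=1)
    cr[1:, 1:] = np.cumsum(np.cumsum(recomb, axis=0), axis=1)

    def _count(c: np.ndarray, i: int, j: int) -> float:
        return c[j + 1, j + 1] - c[i, j + 1] - c[j + 1, i] + c[i, i]

    ii, jj = np.nonzero(strong)
    spans = sub.positions[jj] - sub.positions[ii]
    ok_span = spans <= max_span
    ii, jj, spans = ii[ok_span], jj[ok_span], spans[ok_span]
    candidates = []
    for i, j, sp in zip(ii, jj, spans):
        s = _count(cs, i, j)
        r = _count(cr, i, j)
        inform = s + r
        if inform > 0 and s / inform >= inform_frac:
            candidates.append((int(sp), int(i), int(j)))
    # greedy: span desc, then leftmost start
    candidates.sort(key=lambda t: (-t[0], t[1]))
    used = np.zeros(m, dtype=bool)
    blocks: list[LDBlock] = []
    for sp, i, j in candidates:
        if used[i : j + 1].any():
            continue
        used[i : j + 1] = True
        blocks.append(
            LDBlock(
                chrom=sub.chrom,
                start=int(sub.positions[i]),
                end=int(sub.positions[j]),
                snp_count=j - i + 1,
                population=population,
            )
        )
    blocks.sort(key=lambda b: b.start)
    return blocks
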