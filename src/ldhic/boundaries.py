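"""Distances between contact-domain boundaries and LD-block boundaries,
and the permutation test for boundary coincidence/avoidance.

Boundaries are point coordinates: each domain or block contributes its two
edge positions. The permutation null redraws block locations uniformly
(lengths preserved, placements non-overlapping) and recomputes the median
nearest-boundary distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ld import LDBlock

__all__ = [
    "BoundarySet",
    "nearest_boundary_distances",
    "permute_blocks",
    "boundary_permutation_test",
    "block_length_vs_boundary_distance",
]


@dataclass
class BoundarySet:
    """Sorted, deduplicated point boundaries on one chromosome."""

    chrom: str
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.unique(np.asarray(self.positions, dtype=np.int64))

    @classmethod
    def from_intervals(cls, intervals, chrom: str = "chr1") -> "BoundarySet":
        """Each (start, end) interval contributes both edges."""
        pos = [c for s, e in intervals for c in (s, e)]
        return cls(chrom=chrom, positions=np.asarray(pos, dtype=np.int64))

    @classmethod
    def from_blocks(cls, blocks: list[LDBlock]) -> "BoundarySet":
        pos = [c for b in blocks for c in (b.start, b.end)]
        chrom = blocks[0].chrom if blocks else "chr1"
        return cls(chrom=chrom, positions=np.asarray(pos, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.positions)


def _nearest(query: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Min |query - ref| per query point; ref must be sorted non-empty."""
    idx = np.searchsorted(ref, query)
    left = ref[np.clip(idx - 1, 0, ref.size - 1)]
    right = ref[np.clip(idx, 0, ref.size - 1)]
    return np.minimum(np.abs(query - left), np.abs(query - right))


def nearest_boundary_distances(
    domains: BoundarySet, blocks: BoundarySet
) -> tuple[np.ndarray, float]:
    """Distance from each domain boundary to its nearest block boundary,
    and the median of those distances."""
    if len(domains) == 0 or len(blocks) == 0:
        raise ValueError("both boundary sets must be non-empty")
    d = _nearest(domains.positions, blocks.positions)
    return d, float(np.median(d))


def _uniform_placements(
    lengths: np.ndarray, chrom_length: int, rng: np.random.Generator, n_draws: int
) -> np.ndarray:
    """Starts (n_draws, n_blocks) of uniform non-overlapping placements.

    The free space left over by the blocks is split into n+1 gaps by the
    order statistics of uniform draws, which samples the uniform
    distribution over non-overlapping placements directly (no rejection).
    Block order along the chromosome is randomized per draw.
    """
    n = lengths.size
    free = chrom_length - lengths.sum()
    if free < 0:
        raise ValueError("total block length exceeds chromosome length")
    u = np.sort(rng.random((n_draws, n)), axis=1) * free  # gap prefix points
    perm = np.argsort(rng.random((n_draws, n)), axis=1)  # random block order
    ordered_len = lengths[perm]
    starts_ordered = u + np.concatenate(
        [np.zeros((n_draws, 1)), np.cumsum(ordered_len[:, :-1], axis=1)], axis=1
    )
    # undo the ordering so column k is block k's start
    starts = np.empty_like(starts_ordered)
    np.put_along_axis(starts, perm, starts_ordered, axis=1)
    return np.floor(starts).astype(np.int64)


def permute_blocks(
    blocks: list[LDBlock], chrom_length: int, seed: int = 0
) -> list[LDBlock]:
    """Redraw block locations uniformly without overlap, preserving the
    multiset of block lengths."""
    if not blocks:
        return []
    lengths = np.array([b.span for b in blocks], dtype=np.int64)
    rng = np.random.default_rng(seed)
    starts = _uniform_placements(lengths, chrom_length, rng, 1)[0]
    out = [
        LDBlock(
            chrom=b.chrom,
            start=int(s),
            end=int(s + b.span),
            snp_count=b.snp_count,
            population=b.population,
        )
        for b, s in zip(blocks, starts)
    ]
    return sorted(out, key=lambda b: b.start)


def boundary_permutation_test(
    domains: BoundarySet,
    blocks: list[LDBlock],
    chrom_length: int,
    n_perm: int = 1000,
    alternative: str = "longer",
    seed: int = 0,
) -> dict:
    """Permutation test of the observed median domain-to-block boundary
    distance against uniformly re-placed blocks.

    ``alternative="longer"`` asks whether the observed median is longer
    than expected (boundary avoidance); ``"shorter"`` tests coincidence.
    p uses the add-one estimator (1 + #extreme) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if alternative not in ("longer", "shorter"):
        raise ValueError("alternative must be 'longer' or 'shorter'")
    block_bounds = BoundarySet.from_blocks(blocks)
    _, observed = nearest_boundary_distances(domains, block_bounds)
    lengths = np.array([b.span for b in blocks], dtype=np.int64)
    rng = np.random.default_rng(seed)
    starts = _uniform_placements(lengths, chrom_length, rng, n_perm)
    null = np.empty(n_perm)
    q = domains.positions
    for k in range(n_perm):
        bounds = np.sort(np.concatenate([starts[k], starts[k] + lengths]))
        null[k] = np.median(_nearest(q, bounds))
    if alternative == "longer":
        extreme = np.sum(null >= observed)
    else:
        extreme = np.sum(null <= observed)
    p = (1.0 + extreme) / (n_perm + 1.0)
    return {
        "observed_median": observed,
        "null_medians": null,
        "p": float(p),
        "alternative": alternative,
    }


def block_length_vs_boundary_distance(
    blocks: list[LDBlock],
    domains: BoundarySet,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Block length distribution as a function of the distance from the
    block midpoint to the nearest domain boundary.

    Returns one row per distance bin with median and quartiles of block
    length (bp)."""
    if not blocks or len(domains) == 0:
        raise ValueError("non-empty blocks and domains required")
    mids = np.array([(b.start + b.end) // 2 for b in blocks])
    lengths = np.array([b.length for b in blocks], dtype=float)
    dist = _nearest(mids, domains.positions)
    edges = np.linspace(0, dist.max() + 1, n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = lengths[which == b]
        if sel.size == 0:
            continue
        rows.append(
            {
                "dist_low": edges[b],
                "dist_high": edges[b + 1],
                "n_blocks": int(sel.size),
                "length_q25": float(np.percentile(sel, 25)),
                "length_median": float(np.median(sel)),
                "length_q75": float(np.percentile(sel, 75)),
            }
        )
    return pd.DataFrame(rows)
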