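"""Interaction-level LD: SNP-to-anchor assignment, cross-anchor max LD,
significant-versus-matched log ratios, and distance-matched null sets.

Anchors are 0-based half-open bp intervals; SNP positions are 1-based
points, so a SNP at position p lies in [start, end) iff start < p <= end.
Interaction distance is midpoint-to-midpoint in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .ld import LDBlock, LDPairTable

__all__ = [
    "InteractionSet",
    "snps_on_anchors",
    "interaction_max_ld",
    "interaction_ld_log_ratio",
    "shuffle_same_chrom",
    "quantile_distance_match",
    "same_block_fraction",
]

SCORE_THRESHOLD = 5.0  # CHiCAGO convention: score < 5 is a negative


@dataclass
class InteractionSet:
    """Paired-anchor interaction records.

    ``df`` columns: chrom, start1, end1, start2, end2, score, significant,
    distance, kind. For promoter-capture records (kind="pchic") anchor1 is
    the bait and anchor2 the promoter-interacting region (PIR), and
    significance is score >= 5 by convention.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        required = {"chrom", "start1", "end1", "start2", "end2", "score"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"InteractionSet missing columns: {sorted(missing)}")
        if "kind" not in df.columns:
            df["kind"] = "hic"
        if "significant" not in df.columns:
            df["significant"] = df["score"] >= SCORE_THRESHOLD
        if "distance" not in df.columns:
            mid1 = (df["start1"] + df["end1"]) / 2.0
            mid2 = (df["start2"] + df["end2"]) / 2.0
            df["distance"] = (mid2 - mid1).astype(np.int64)
        if len(df) and not (df["start1"] < df["start2"]).all():
            raise ValueError("anchor1 must precede anchor2 (start1 < start2)")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def significant(self) -> "InteractionSet":
        return InteractionSet(self.df[self.df["significant"]].copy())

    @property
    def nonsignificant(self) -> "InteractionSet":
        return InteractionSet(self.df[~self.df["significant"]].copy())


def snps_on_anchors(
    snp_positions: np.ndarray, interactions: InteractionSet
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-interaction index arrays of SNPs falling in each anchor.

    SNP positions must be sorted ascending (1-based); anchors are 0-based
    half-open, so membership is start + 1 <= pos <= end.
    """
    pos = np.asarray(snp_positions)
    if np.any(np.diff(pos) < 0):
        raise ValueError("snp_positions must be sorted")
    df = interactions.df
    out = []
    for s1, e1, s2, e2 in zip(df["start1"], df["end1"], df["start2"], df["end2"]):
        a = np.arange(np.searchsorted(pos, s1 + 1), np.searchsorted(pos, e1, "right"))
        b = np.arange(np.searchsorted(pos, s2 + 1), np.searchsorted(pos, e2, "right"))
        out.append((a, b))
    return out


def _pair_matrix(pairs: LDPairTable, snp_positions: np.ndarray) -> sparse.csr_matrix:
    """Stored r² values as a sparse SNP-index matrix (upper entries only)."""
    pos = np.asarray(snp_positions)
    m = pos.size
    if len(pairs) == 0:
        return sparse.csr_matrix((m, m))
    i = np.searchsorted(pos, pairs.df["pos_i"].to_numpy())
    j = np.searchsorted(pos, pairs.df["pos_j"].to_numpy())
    ok = (
        (i < m) & (j < m)
        & (pos[np.minimum(i, m - 1)] == pairs.df["pos_i"].to_numpy())
        & (pos[np.minimum(j, m - 1)] == pairs.df["pos_j"].to_numpy())
    )
    return sparse.csr_matrix(
        (pairs.df["r2"].to_numpy()[ok], (i[ok], j[ok])), shape=(m, m)
    )


def interaction_max_ld(
    interactions: InteractionSet,
    pairs: LDPairTable,
    snp_positions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum stored r² across cross-anchor SNP pairs, per interaction.

    Pairs absent from storage (below the floor) contribute 0. Returns
    (max_ld, no_snp_pair flag); interactions with an empty anchor get
    max_ld 0 and the flag set.
    """
    pos = np.asarray(snp_positions)
    mat = _pair_matrix(pairs, pos)
    mat = mat.maximum(mat.T).tocsr()
    anchors = snps_on_anchors(pos, interactions)
    max_ld = np.zeros(len(interactions))
    no_pair = np.zeros(len(interactions), dtype=bool)
    for k, (a, b) in enumerate(anchors):
        if a.size == 0 or b.size == 0:
            no_pair[k] = True
            continue
        sub = mat[a[0] : a[-1] + 1, b[0] : b[-1] + 1]
        max_ld[k] = sub.max() if sub.nnz else 0.0
    return max_ld, no_pair


def interaction_ld_log_ratio(
    positives: InteractionSet,
    negatives: InteractionSet,
    pairs: LDPairTable,
    snp_positions: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    drop_no_snp: bool = False,
) -> dict:
    """Natural-log ratio of mean per-interaction max LD, positives over
    negatives, with a nonparametric bootstrap CI over interactions.

    Interactions lacking a cross-anchor SNP pair contribute max LD 0 by
    default; ``drop_no_snp`` removes them instead.
    """
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("both interaction sets must be non-empty")
    vp, fp = interaction_max_ld(positives, pairs, snp_positions)
    vn, fn = interaction_max_ld(negatives, pairs, snp_positions)
    if drop_no_snp:
        vp, vn = vp[~fp], vn[~fn]
        if vp.size == 0 or vn.size == 0:
            raise ValueError("no interactions with SNPs on both anchors")
    mean_pos = float(vp.mean())
    mean_neg = float(vn.mean())
    if mean_neg == 0:
        raise ValueError("mean negative LD is 0 (no SNPs on negatives?)")
    if mean_pos == 0:
        raise ValueError("mean positive LD is 0 (no SNPs on positives?)")
    rng = np.random.default_rng(seed)
    bp = vp[rng.integers(0, vp.size, size=(n_boot, vp.size))].mean(axis=1)
    bn = vn[rng.integers(0, vn.size, size=(n_boot, vn.size))].mean(axis=1)
    with np.errstate(divide="ignore"):
        boots = np.log(bp) - np.log(bn)
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "mean_pos": mean_pos,
        "mean_neg": mean_neg,
        "log_ratio": float(np.log(mean_pos / mean_neg)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_pos": int(vp.size),
        "n_neg": int(vn.size),
    }


def shuffle_same_chrom(
    interactions: InteractionSet,
    chrom_length: int,
    seed: int = 0,
    avoid: InteractionSet | None = None,
    max_attempts: int = 100,
) -> InteractionSet:
    """Distance-matched shuffle along the same chromosome.

    Each record is jointly shifted to a uniform random position, preserving
    both anchor lengths and their separation (hence per-record distance is
    exactly preserved). Shifted records overlapping any anchor of ``avoid``
    are redrawn, up to ``max_attempts`` per record.
    """
    df = interactions.df
    extents = (df["end2"] - df["start1"]).to_numpy()
    if len(df) and extents.max() > chrom_length:
        raise ValueError("chromosome shorter than an interaction's extent")
    forbid: list[tuple[int, int]] = []
    if avoid is not None:
        a = avoid.df
        forbid = sorted(
            list(zip(a["start1"], a["end1"])) + list(zip(a["start2"], a["end2"]))
        )
    fstart = np.array([s for s, _ in forbid])
    fend = np.array([e for _, e in forbid])
    rng = np.random.default_rng(seed)
    new_rows = df.copy()
    for idx in range(len(df)):
        row = df.iloc[idx]
        ext = int(extents[idx])
        placed = False
        for _ in range(max_attempts):
            ns1 = int(rng.integers(0, chrom_length - ext + 1))
            delta = ns1 - int(row["start1"])
            iv = [
                (row["start1"] + delta, row["end1"] + delta),
                (row["start2"] + delta, row["end2"] + delta),
            ]
            if forbid:
                hit = any(np.any((fstart < e) & (fend > s)) for s, e in iv)
                if hit:
                    continue
            for col, shift in (("start1", delta), ("end1", delta),
                               ("start2", delta), ("end2", delta)):
                new_rows.iat[idx, new_rows.columns.get_loc(col)] = row[col] + shift
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place shuffled interaction {idx}")
    new_rows["score"] = 0.0
    new_rows["significant"] = False
    return InteractionSet(new_rows)


def quantile_distance_match(
    positives: InteractionSet,
    candidates: InteractionSet,
    n_bins: int = 20,
    seed: int = 0,
) -> InteractionSet:
    """Sample non-significant candidates to match the positives' distance
    distribution via quantile binning."""
    if candidates.df["significant"].any():
        raise ValueError("candidates must be non-significant")
    pd_ = positives.df["distance"].to_numpy()
    cd = candidates.df["distance"].to_numpy()
    edges = np.quantile(pd_, np.linspace(0.0, 1.0, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    pos_bin = np.searchsorted(edges, pd_, side="right") - 1
    cand_bin = np.searchsorted(edges, cd, side="right") - 1
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for b in range(n_bins):
        need = int(np.sum(pos_bin == b))
        if need == 0:
            continue
        pool = np.flatnonzero(cand_bin == b)
        if pool.size < need:
            lo = edges[b] if np.isfinite(edges[b]) else pd_.min()
            hi = edges[b + 1] if np.isfinite(edges[b + 1]) else pd_.max()
            raise ValueError(
                f"not enough candidates in distance bin [{lo:.0f}, {hi:.0f}]: "
                f"need {need}, have {pool.size}"
            )
        chosen.append(rng.choice(pool, size=need, replace=False))
    idx = np.concatenate(chosen) if chosen else np.array([], dtype=int)
    return InteractionSet(candidates.df.iloc[np.sort(idx)].copy())


def same_block_fraction(
    interactions: InteractionSet, blocks: list[LDBlock]
) -> float:
    """Fraction of interactions whose two anchors are overlapped by one
    common LD block. Block coordinates (1-based inclusive) are converted to
    0-based half-open for the overlap test."""
    if len(interactions) == 0:
        return 0.0
    if not blocks:
        return 0.0
    bs = np.array([b.start - 1 for b in blocks])
    be = np.array([b.end for b in blocks])
    df = interactions.df
    hit = 0
    for s1, e1, s2, e2 in zip(df["start1"], df["end1"], df["start2"], df["end2"]):
        both = (bs < e1) & (be > s1) & (bs < e2) & (be > s2)
        if both.any():
            hit += 1
    return hit / len(df)
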