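"""Multi-scale concordance of LD and chromatin contact maps.

A bin-pair track carries, per 5-kb bin pair, the 75th percentile of SNP
pair r² spanning the two bins and the O/E contact value. Concordance asks,
within non-overlapping genomic windows of a given size, how often strong
LD (r² summary > 0.8) and frequent contact (top quartile) co-occur versus
the independence expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .boundaries import _nearest  # nearest-point helper
from .hic import ContactMatrix
from .interactions import InteractionSet
from .ld import LDBlock, LDPairTable

__all__ = [
    "BinPairTrack",
    "build_bin_pair_track",
    "concordance_by_window",
    "decay_profile",
    "blocks_spanned",
    "DEFAULT_WINDOW_SIZES",
]

# the nine analysis scales, in bp
DEFAULT_WINDOW_SIZES = tuple(w * 1000 for w in
                             (5, 10, 20, 40, 80, 160, 320, 640, 1280))


@dataclass
class BinPairTrack:
    """Aligned LD and contact values per bin pair (bin_i < bin_j)."""

    bin_size: int
    df: pd.DataFrame  # columns bin_i, bin_j, ld_summary, contact_value
    chrom: str = "chr1"

    def __len__(self) -> int:
        return len(self.df)


def _padded_percentile(
    sorted_vals: np.ndarray,
    group_start: np.ndarray,
    group_size: np.ndarray,
    totals: np.ndarray,
    q: float,
) -> np.ndarray:
    """Linear-interpolation percentile per group where each group consists
    of ``totals - group_size`` implicit zeros followed by ``group_size``
    stored values sorted ascending (all nonnegative)."""
    t = q / 100.0 * (totals - 1.0)
    f = np.floor(t).astype(np.int64)
    frac = t - f

    def value_at(rank: np.ndarray) -> np.ndarray:
        off = rank - (totals - group_size)  # index into stored values
        out = np.zeros(rank.shape)
        has = off >= 0
        idx = group_start + np.clip(off, 0, np.maximum(group_size - 1, 0))
        out[has] = sorted_vals[idx[has].astype(np.int64)]
        return out

    lo = value_at(f)
    hi = value_at(np.minimum(f + 1, totals - 1))
    return lo + frac * (hi - lo)


def build_bin_pair_track(
    pairs: LDPairTable,
    oe: ContactMatrix,
    bin_size: int = 5000,
    snp_positions: np.ndarray | None = None,
    ld_percentile: float = 75.0,
    max_bin_dist: int | None = None,
    include_floor_zeros: bool = True,
) -> BinPairTrack:
    """Aggregate SNP-pair LD and O/E contacts onto common bin pairs.

    ``ld_summary`` is the 75th percentile of r² over SNP pairs whose SNPs
    fall in the respective bins. When ``snp_positions`` is supplied and
    ``include_floor_zeros`` is True, SNP pairs omitted from storage (below
    the r² floor) enter the percentile as zeros, mirroring the assignment
    of r² = 0 to sub-threshold pairs. ``contact_value`` is the O/E entry
    (structural zeros between included bins count as 0). Bin pairs with
    neither value are dropped.
    """
    if max_bin_dist is None:
        max_bin_dist = max(DEFAULT_WINDOW_SIZES) // bin_size
    df = pairs.df
    bi = (df["pos_i"].to_numpy() - 1) // bin_size
    bj = (df["pos_j"].to_numpy() - 1) // bin_size
    same = bi == bj
    bi, bj = bi[~same], bj[~same]
    r2 = df["r2"].to_numpy()[~same]
    key = bi * (10 ** 9) + bj

    order = np.lexsort((r2, key))
    key_s, r2_s = key[order], r2[order]
    uniq, start, count = np.unique(key_s, return_index=True, return_counts=True)

    if snp_positions is not None and include_floor_zeros:
        sbin = (np.asarray(snp_positions) - 1) // bin_size
        per_bin = np.bincount(sbin, minlength=int(sbin.max()) + 1 if sbin.size else 0)
        totals = (per_bin[(uniq // 10 ** 9).astype(np.int64)]
                  * per_bin[(uniq % 10 ** 9).astype(np.int64)]).astype(float)
        totals = np.maximum(totals, count)  # guard against position mismatch
    else:
        totals = count.astype(float)
    ld_summary = _padded_percentile(r2_s, start, count.astype(float),
                                    totals, ld_percentile)
    ld_bi = (uniq // 10 ** 9).astype(np.int64)
    ld_bj = (uniq % 10 ** 9).astype(np.int64)

    # contact values: all included-bin pairs within max_bin_dist, with
    # structural zeros, at distances where expected is defined
    included = oe.included_mask()
    n_bins = oe.n_bins
    exp_def = np.ones(n_bins, dtype=bool)
    if oe.expected is not None:
        exp_def = oe.expected > 0
    dense = np.zeros((n_bins, n_bins))
    dense[oe.bins_i, oe.bins_j] = oe.values
    ci, cj, cv = [], [], []
    for d in range(1, min(max_bin_dist, n_bins - 1) + 1):
        if not exp_def[d]:
            continue
        ii = np.arange(0, n_bins - d)
        jj = ii + d
        ok = included[ii] & included[jj]
        ci.append(ii[ok])
        cj.append(jj[ok])
        cv.append(dense[ii[ok], jj[ok]])
    contact = pd.DataFrame({
        "bin_i": np.concatenate(ci) if ci else np.array([], dtype=int),
        "bin_j": np.concatenate(cj) if cj else np.array([], dtype=int),
        "contact_value": np.concatenate(cv) if cv else np.array([]),
    })
    ldf = pd.DataFrame({"bin_i": ld_bi, "bin_j": ld_bj, "ld_summary": ld_summary})
    ldf = ldf[(ldf["bin_j"] - ldf["bin_i"]) <= max_bin_dist]
    merged = contact.merge(ldf, on=["bin_i", "bin_j"], how="outer")
    merged = merged.dropna(how="all", subset=["ld_summary", "contact_value"])
    merged = merged.sort_values(["bin_i", "bin_j"]).reset_index(drop=True)
    return BinPairTrack(bin_size=bin_size, df=merged, chrom=oe.chrom)


def concordance_by_window(
    track: BinPairTrack,
    window_sizes=DEFAULT_WINDOW_SIZES,
    ld_thresh: float = 0.8,
    contact_pct: float = 75.0,
    expected_mode: str = "product",
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed versus independence-expected co-occurrence of strong LD
    and frequent contact, per window size.

    For each window size the chromosome is partitioned into consecutive
    non-overlapping windows; bin pairs with both bins in the same window
    and both values present are collected. The frequent-contact threshold
    is the ``contact_pct`` percentile of the collected contact values
    (one threshold per window-size analysis). observed = fraction with
    both flags.

    ``expected_mode`` selects the independence expectation:

    - ``"product"``: product of the two marginal fractions. Both masks
      decay with genomic distance, so this expected carries a
      distance-confounding bias even when LD and contacts are unrelated.
    - ``"distance_matched"``: product of the marginals within each
      bin-separation stratum, averaged over strata — the analytic
      expectation of shuffling the contact mask across bin pairs at fixed
      distance. Unbiased under distance-respecting independence.
    - ``"permutation"``: the same construction by explicit seeded
      shuffles (``n_perm`` rounds).
    """
    if len(track) == 0:
        raise ValueError("empty track")
    if expected_mode not in ("product", "distance_matched", "permutation"):
        raise ValueError(f"unknown expected_mode: {expected_mode}")
    df = track.df.dropna(subset=["ld_summary", "contact_value"])
    rng = np.random.default_rng(seed)
    rows = []
    for w in window_sizes:
        if w < track.bin_size:
            raise ValueError("window smaller than bin size")
        win_i = (df["bin_i"].to_numpy() * track.bin_size) // w
        win_j = (df["bin_j"].to_numpy() * track.bin_size) // w
        sel = df[win_i == win_j]
        n = len(sel)
        if n == 0:
            rows.append({"window_size": w, "n_pairs": 0,
                         "observed": np.nan, "expected": np.nan})
            continue
        contact_thresh = np.percentile(sel["contact_value"], contact_pct)
        strong = sel["ld_summary"].to_numpy() > ld_thresh
        frequent = sel["contact_value"].to_numpy() > contact_thresh
        observed = float(np.mean(strong & frequent))
        if expected_mode == "product":
            expected = float(np.mean(strong) * np.mean(frequent))
        else:
            dist = (sel["bin_j"] - sel["bin_i"]).to_numpy()
            if expected_mode == "distance_matched":
                acc = 0.0
                for d in np.unique(dist):
                    at = dist == d
                    acc += at.sum() * strong[at].mean() * frequent[at].mean()
                expected = float(acc / n)
            else:  # permutation
                acc = 0.0
                shuffled = frequent.copy()
                order = np.argsort(dist, kind="stable")
                for _ in range(n_perm):
                    for d in np.unique(dist):
                        at = np.flatnonzero(dist == d)
                        shuffled[at] = frequent[rng.permutation(at)]
                    acc += np.mean(strong & shuffled)
                expected = float(acc / n_perm)
        rows.append({"window_size": w, "n_pairs": n,
                     "observed": observed, "expected": expected})
    return pd.DataFrame(rows)


def decay_profile(
    pairs: LDPairTable,
    matrix: ContactMatrix,
    max_dist: int = 2_000_000,
    dist_bins: int = 40,
) -> tuple[pd.DataFrame, dict]:
    """Distance decay of LD and contact frequency.

    Per equal-width distance bin: median stored (nonzero) r² and mean
    nonzero normalized contact. Spearman rank correlations with distance
    are computed over the raw, unbinned nonzero values of each measure.
    """
    ld_d = pairs.df["distance"].to_numpy().astype(float)
    ld_v = pairs.df["r2"].to_numpy()
    cm_d = ((matrix.bins_j - matrix.bins_i) * matrix.bin_size).astype(float)
    cm_v = matrix.values
    keep_ld = ld_d <= max_dist
    keep_cm = (cm_d <= max_dist) & (cm_d > 0) & (cm_v > 0)
    ld_d, ld_v = ld_d[keep_ld], ld_v[keep_ld]
    cm_d, cm_v = cm_d[keep_cm], cm_v[keep_cm]
    edges = np.linspace(0, max_dist, dist_bins + 1)
    rows = []
    for b in range(dist_bins):
        in_ld = (ld_d >= edges[b]) & (ld_d < edges[b + 1])
        in_cm = (cm_d >= edges[b]) & (cm_d < edges[b + 1])
        rows.append({
            "dist_low": edges[b],
            "dist_high": edges[b + 1],
            "median_r2": float(np.median(ld_v[in_ld])) if in_ld.any() else np.nan,
            "mean_contact": float(np.mean(cm_v[in_cm])) if in_cm.any() else np.nan,
            "n_ld": int(in_ld.sum()),
            "n_contact": int(in_cm.sum()),
        })
    rho = {}
    for name, (d, v) in (("ld", (ld_d, ld_v)), ("contact", (cm_d, cm_v))):
        if d.size >= 2 and np.unique(v).size > 1 and np.unique(d).size > 1:
            rho[name] = float(stats.spearmanr(d, v).statistic)
        else:
            rho[name] = 0.0
    return pd.DataFrame(rows), rho


def blocks_spanned(
    interactions: InteractionSet, blocks: list[LDBlock]
) -> np.ndarray:
    """Number of LD blocks wholly contained in the open interval between
    the two anchor midpoints, per interaction."""
    if not blocks:
        return np.zeros(len(interactions), dtype=int)
    starts = np.sort(np.array([b.start for b in blocks]))
    order = np.argsort([b.start for b in blocks])
    ends = np.array([b.end for b in blocks])[order]
    # blocks sorted by start; use cumulative max of ends for containment
    df = interactions.df
    mid1 = ((df["start1"] + df["end1"]) // 2).to_numpy()
    mid2 = ((df["start2"] + df["end2"]) // 2).to_numpy()
    out = np.empty(len(df), dtype=int)
    for k, (lo, hi) in enumerate(zip(mid1, mid2)):
        out[k] = int(np.sum((starts > lo) & (ends < hi)))
    return out
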