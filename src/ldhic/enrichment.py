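"""eQTL enrichment across distance bins and GO-term enrichment contrasts
between SNP-to-gene mapping strategies.

The eQTL contrast asks whether eQTL SNP-gene links concentrate in
statistically significant chromatin interactions, stratified by genomic
distance. The GO contrast compares three ways of assigning GWAS SNPs to
genes — nearest gene, all genes in the SNP's LD block, and promoter-capture
bait genes whose PIR contains the SNP — by Fisher exact tests with
Benjamini-Hochberg control within each phenotype x strategy family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .interactions import InteractionSet, interaction_max_ld
from .ld import LDBlock, LDPairTable

__all__ = [
    "GeneAnnotation",
    "GOAnnotation",
    "EnrichmentResult",
    "interaction_feature_vectors",
    "quantile_distance_bins",
    "stratified_or",
    "fisher_exact_2x2",
    "bh_adjust",
    "snp_to_genes",
    "go_enrichment_compare",
]

log = logging.getLogger(__name__)


@dataclass
class GeneAnnotation:
    """Gene TSS/promoter coordinates plus (optional) bait-fragment mapping.

    ``df`` columns: gene_id, tss, promoter_start, promoter_end,
    bait_start, bait_end (bait columns may hold NaN for unbaited genes).
    Promoters and baits are 0-based half-open intervals.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "tss", "promoter_start", "promoter_end"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"GeneAnnotation missing columns: {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def bait_gene(self, start: int, end: int) -> str | None:
        """Gene whose bait fragment equals [start, end); None if absent."""
        m = self.df[(self.df["bait_start"] == start) & (self.df["bait_end"] == end)]
        if len(m) == 0:
            return None
        return str(m.sort_values("gene_id")["gene_id"].iloc[0])


class GOAnnotation:
    """gene_id -> set of GO term ids (empty sets are not stored)."""

    def __init__(self, mapping: dict[str, set[str]]):
        self.mapping = {g: set(t) for g, t in mapping.items() if t}

    def terms_of(self, gene: str) -> set[str]:
        return self.mapping.get(gene, set())

    def all_terms(self) -> list[str]:
        out: set[str] = set()
        for t in self.mapping.values():
            out |= t
        return sorted(out)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class EnrichmentResult:
    """One 2x2 enrichment contrast: counts, odds ratio, Wald CI, p, q."""

    stratum: str
    a: int
    b: int
    c: int
    d: int
    or_estimate: float
    log_or: float
    ci_low: float
    ci_high: float
    p: float
    q: float = float("nan")
    note: str = ""


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Returns (sample odds ratio ad/bc, p). p sums hypergeometric
    probabilities of all tables with the observed margins whose probability
    does not exceed the observed table's.
    """
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise ValueError("all margins must be positive")
    with np.errstate(divide="ignore"):
        sample_or = np.inf if b * c == 0 else (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(sample_or), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, original order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def quantile_distance_bins(
    interactions: InteractionSet,
    max_dist: int = 2_000_000,
    n_bins: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile distance bins up to ``max_dist``.

    Returns (bin label per retained interaction, boolean retained mask).
    Interactions beyond ``max_dist`` are dropped with a logged count;
    degenerate (tied) quantile edges raise.
    """
    dist = interactions.df["distance"].to_numpy()
    keep = dist <= max_dist
    dropped = int(np.sum(~keep))
    if dropped:
        log.info("quantile_distance_bins: dropped %d interactions beyond %d bp",
                 dropped, max_dist)
    d = dist[keep]
    if d.size < n_bins:
        raise ValueError("fewer interactions than requested bins")
    edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    if np.unique(edges).size != edges.size:
        raise ValueError("tied distance quantiles produce empty bins")
    labels = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    return labels, keep


def stratified_or(
    y: np.ndarray, x: np.ndarray, bins: np.ndarray, z: float = 1.959963984540054
) -> list[EnrichmentResult]:
    """Per-stratum odds ratio of y on x with Wald CI.

    OR = ad/bc with the Haldane-Anscombe 0.5 correction applied to all
    cells when any cell is zero; p from the Wald z on log OR. With one
    binary covariate this equals the logistic-regression estimate.
    Strata with a single x class yield an NA result with a reason.
    """
    y = np.asarray(y, dtype=bool)
    x = np.asarray(x, dtype=bool)
    bins = np.asarray(bins)
    out: list[EnrichmentResult] = []
    for b in np.unique(bins):
        sel = bins == b
        xs, ys = x[sel], y[sel]
        if xs.all() or (~xs).all():
            out.append(EnrichmentResult(str(b), 0, 0, 0, 0, np.nan, np.nan,
                                        np.nan, np.nan, np.nan,
                                        note="single x class in stratum"))
            continue
        a = int(np.sum(xs & ys))
        bb = int(np.sum(xs & ~ys))
        c = int(np.sum(~xs & ys))
        d = int(np.sum(~xs & ~ys))
        cells = np.array([a, bb, c, d], dtype=float)
        if (cells == 0).any():
            cells = cells + 0.5
        or_est = (cells[0] * cells[3]) / (cells[1] * cells[2])
        log_or = float(np.log(or_est))
        se = float(np.sqrt((1.0 / cells).sum()))
        lo, hi = np.exp(log_or - z * se), np.exp(log_or + z * se)
        p = float(2.0 * stats.norm.sf(abs(log_or) / se))
        out.append(EnrichmentResult(str(b), a, bb, c, d, float(or_est),
                                    log_or, float(lo), float(hi), p))
    return out


def interaction_feature_vectors(
    interactions: InteractionSet,
    eqtls: pd.DataFrame,
    annotation: GeneAnnotation,
    pairs: LDPairTable | dict[str, LDPairTable],
    snp_positions: np.ndarray,
    ld_thresh: float = 0.8,
) -> pd.DataFrame:
    """Per-interaction flags used in the eQTL enrichment contrasts.

    - ``has_eqtl``: some eQTL SNP lies in the PIR (anchor2) and the eQTL
      target gene's bait fragment equals this interaction's bait.
    - ``significant``: the interaction's significance flag.
    - ``closest_gene_in_bait``: the gene nearest the PIR (promoter interval
      distance; ties broken by smaller gene_id) has this bait fragment.
    - ``strong_ld``: cross-anchor max r² > ``ld_thresh`` in any population
      (``pairs`` may be one table or a mapping population -> table).
    """
    adf = annotation.df
    known = set(adf["gene_id"])
    missing = sorted(set(eqtls["gene_id"]) - known)
    if missing:
        raise ValueError(f"eQTL target genes absent from annotation: {missing}")
    gene_bait = {
        str(r.gene_id): (r.bait_start, r.bait_end)
        for r in adf.itertuples()
        if not (pd.isna(r.bait_start) or pd.isna(r.bait_end))
    }
    eq_pos = eqtls["snp_pos"].to_numpy()
    eq_gene = eqtls["gene_id"].to_numpy()
    order = np.argsort(eq_pos)
    eq_pos, eq_gene = eq_pos[order], eq_gene[order]

    prom_s = adf["promoter_start"].to_numpy()
    prom_e = adf["promoter_end"].to_numpy()
    gene_ids = adf["gene_id"].to_numpy()

    tables = pairs if isinstance(pairs, dict) else {"__one__": pairs}
    strong = np.zeros(len(interactions), dtype=bool)
    for tab in tables.values():
        ml, _ = interaction_max_ld(interactions, tab, snp_positions)
        strong |= ml > ld_thresh

    rows = []
    df = interactions.df
    for k, r in enumerate(df.itertuples()):
        bait = (r.start1, r.end1)
        # eQTL SNP in PIR (1-based point in 0-based half-open interval)
        loi = np.searchsorted(eq_pos, r.start2 + 1)
        hii = np.searchsorted(eq_pos, r.end2, side="right")
        has_eqtl = any(
            gene_bait.get(str(g)) == bait for g in eq_gene[loi:hii]
        )
        # closest gene to the PIR by promoter interval distance
        gap = np.maximum(prom_s - r.end2, r.start2 - prom_e)
        gap = np.maximum(gap, 0)
        best = np.flatnonzero(gap == gap.min())
        best_gene = min(str(gene_ids[i]) for i in best)
        closest_in_bait = gene_bait.get(best_gene) == bait
        rows.append(
            {
                "has_eqtl": has_eqtl,
                "significant": bool(r.significant),
                "closest_gene_in_bait": bool(closest_in_bait),
                "strong_ld": bool(strong[k]),
                "distance": int(r.distance),
            }
        )
    return pd.DataFrame(rows)


def snp_to_genes(
    snps: np.ndarray,
    strategy: str,
    annotation: GeneAnnotation,
    blocks: list[LDBlock] | None = None,
    interactions: InteractionSet | None = None,
) -> list[set[str]]:
    """Map each SNP position to a gene set under one of three strategies.

    - ``closest``: the single gene with nearest promoter (interval
      distance; tie -> smaller gene_id).
    - ``ld_block``: all genes whose promoter overlaps the SNP's containing
      LD block (empty set if the SNP is in no block).
    - ``pchic``: bait genes of significant interactions whose PIR contains
      the SNP.
    """
    snps = np.asarray(snps)
    adf = annotation.df
    prom_s = adf["promoter_start"].to_numpy()
    prom_e = adf["promoter_end"].to_numpy()
    gene_ids = adf["gene_id"].astype(str).to_numpy()
    out: list[set[str]] = []
    if strategy == "closest":
        for p in snps:
            # distance from the 0-based point p-1 to the promoter interval
            gap = np.maximum(np.maximum(prom_s - (p - 1), (p - 1) - (prom_e - 1)), 0)
            best = np.flatnonzero(gap == gap.min())
            out.append({min(gene_ids[i] for i in best)})
    elif strategy == "ld_block":
        if blocks is None:
            raise ValueError("ld_block strategy requires blocks")
        bs = np.array([b.start for b in blocks], dtype=np.int64)
        be = np.array([b.end for b in blocks], dtype=np.int64)
        for p in snps:
            inside = (bs <= p) & (p <= be)
            genes: set[str] = set()
            for bi in np.flatnonzero(inside):
                # promoter (0-based half-open) overlaps block (1-based incl.)
                ov = (prom_s < be[bi]) & (prom_e > bs[bi] - 1)
                genes |= set(gene_ids[ov])
            out.append(genes)
    elif strategy == "pchic":
        if interactions is None:
            raise ValueError("pchic strategy requires interactions")
        sig = interactions.significant.df
        for p in snps:
            genes = set()
            inside = (sig["start2"] < p) & (p <= sig["end2"])
            for r in sig[inside].itertuples():
                g = annotation.bait_gene(int(r.start1), int(r.end1))
                if g is not None:
                    genes.add(g)
            out.append(genes)
    else:
        raise ValueError(f"unknown strategy: {strategy}")
    return out


def go_enrichment_compare(
    gwas: dict[str, np.ndarray],
    annotation: GeneAnnotation,
    go: GOAnnotation,
    blocks: list[LDBlock] | None = None,
    interactions: InteractionSet | None = None,
    strategies: tuple[str, ...] = ("closest", "ld_block", "pchic"),
    fdr_levels: tuple[float, ...] = (0.01, 0.05, 0.10),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GO-term enrichment per (phenotype, strategy, term).

    For the pchic strategy the unit is the significant interaction: the
    2x2 crosses "phenotype SNP in PIR" with "bait gene carries the term".
    For closest/ld_block the unit is the gene: "assigned to the phenotype"
    crosses "carries the term". BH is applied within each
    phenotype x strategy family across terms.

    Returns (long results table, per phenotype/strategy/level counts of
    significant terms).
    """
    if len(go) == 0 or not gwas:
        raise ValueError("non-empty GWAS table and GO annotation required")
    terms = go.all_terms()
    adf = annotation.df
    all_genes = adf["gene_id"].astype(str).to_numpy()
    rows = []
    for phen, snps in gwas.items():
        snps = np.asarray(snps)
        for strategy in strategies:
            if strategy == "pchic":
                if interactions is None:
                    raise ValueError("pchic strategy requires interactions")
                sig = interactions.significant.df
                bait_genes = np.array([
                    annotation.bait_gene(int(r.start1), int(r.end1)) or ""
                    for r in sig.itertuples()
                ])
                has_snp = np.zeros(len(sig), dtype=bool)
                s2 = sig["start2"].to_numpy()
                e2 = sig["end2"].to_numpy()
                for p in snps:
                    has_snp |= (s2 < p) & (p <= e2)
                unit_flag = has_snp
                unit_terms = [go.terms_of(g) for g in bait_genes]
            else:
                mapped = snp_to_genes(snps, strategy, annotation,
                                      blocks=blocks, interactions=interactions)
                assigned: set[str] = set().union(*mapped) if mapped else set()
                unit_flag = np.array([g in assigned for g in all_genes])
                unit_terms = [go.terms_of(g) for g in all_genes]
            if not unit_flag.any():
                rows.append({"phenotype": phen, "strategy": strategy,
                             "term": None, "a": 0, "b": 0, "c": 0, "d": 0,
                             "or": np.nan, "p": np.nan, "q": np.nan,
                             "note": "no mapped units"})
                continue
            pvals, recs = [], []
            for term in terms:
                has_term = np.array([term in t for t in unit_terms])
                a = int(np.sum(unit_flag & has_term))
                b = int(np.sum(unit_flag & ~has_term))
                c = int(np.sum(~unit_flag & has_term))
                d = int(np.sum(~unit_flag & ~has_term))
                try:
                    or_est, p = fisher_exact_2x2(a, b, c, d)
                except ValueError:
                    or_est, p = np.nan, 1.0
                pvals.append(p)
                recs.append((term, a, b, c, d, or_est, p))
            qvals = bh_adjust(pvals)
            for (term, a, b, c, d, or_est, p), q in zip(recs, qvals):
                rows.append({"phenotype": phen, "strategy": strategy,
                             "term": term, "a": a, "b": b, "c": c, "d": d,
                             "or": or_est, "p": p, "q": q, "note": ""})
    results = pd.DataFrame(rows)
    counts = []
    for (phen, strategy), grp in results.dropna(subset=["term"]).groupby(
        ["phenotype", "strategy"]
    ):
        for level in fdr_levels:
            counts.append({"phenotype": phen, "strategy": strategy,
                           "fdr_level": level,
                           "n_significant": int(np.sum(grp["q"] < level))})
    return results, pd.DataFrame(counts)
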