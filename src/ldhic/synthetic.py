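"""Synthetic genotype panels, contact maps, interaction calls and
regulatory fixtures with planted, machine-readable truth.

The haplotype generator is a founder-mosaic model: founders are i.i.d.
Bernoulli(0.5) haplotypes, each sample copies one founder and resamples its
founder between consecutive SNPs with a background probability, or a much
larger probability when a recombination hotspot falls in the interval.
This gives direct local control over LD-block boundaries. The contact map
is a Poisson draw around a power-law distance decay with multiplicative
domain and loop boosts and lognormal per-bin bias — the statistical
skeleton of a deeply sequenced Hi-C map at 5-kb resolution. Interaction
calls mimic promoter-capture scoring with the conventional significance
threshold of 5. Regulatory fixtures plant eQTL odds ratios (proximal vs
distal at 200 kb) and one enriched GO term for one phenotype.

Three coupling scenarios tie (or untie) the genetic and physical maps:
``independent`` places hotspots and domains independently;
``boundary_coincident`` puts hotspots exactly at domain boundaries;
``anchor_ld`` additionally plants perfect-LD SNP pairs across the anchors
of the focal loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .enrichment import GeneAnnotation, GOAnnotation
from .hic import ContactMatrix, expected_by_distance, observed_over_expected, vc_normalize
from .interactions import SCORE_THRESHOLD, InteractionSet
from .ld import HaplotypePanel

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_haplotypes",
    "simulate_contact_map",
    "simulate_interaction_calls",
    "simulate_regulatory_fixtures",
    "random_interactions",
    "make_gene_annotation",
    "default_config",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic genome, with the study's conditions as
    defaults: 5-kb bins, MAF floor 5%, CHiCAGO-style score threshold 5.
    """

    n_haplotypes: int = 2000
    n_snps: int = 512
    chrom_length: int = 2_560_000
    chrom: str = "chr1"
    founder_count: int = 2
    hotspot_positions: tuple[int, ...] = ()
    background_switch_rate: float = 5e-4
    hotspot_switch_rate: float = 0.5
    maf_floor: float = 0.05
    bin_size: int = 5000
    alpha: float = 1.0
    domain_intervals: tuple[tuple[int, int], ...] = ()
    domain_boost: float = 2.0
    loop_anchors: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = ()
    loop_boost: float = 5.0
    bias_sd: float = 0.3
    depth: float = 2_000_000.0
    coupling: str = "independent"
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.background_switch_rate, self.hotspot_switch_rate,
                     self.maf_floor):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.coupling not in ("independent", "boundary_coincident", "anchor_ld"):
            raise ValueError(f"unknown coupling: {self.coupling}")
        doms = sorted(self.domain_intervals)
        for (s1, e1), (s2, e2) in zip(doms, doms[1:]):
            if e1 > s2:
                raise ValueError("domain intervals must be non-overlapping")
        self.domain_intervals = tuple(doms)
        for (a, b) in self.loop_anchors:
            if not a[0] < b[0]:
                raise ValueError("loop anchors must be ordered start1 < start2")


@dataclass
class SyntheticTruth:
    """Machine-readable record of everything the generator planted."""

    hotspot_positions: tuple[int, ...] = ()
    domain_boundaries: tuple[int, ...] = ()
    loop_anchor_pairs: tuple = ()
    eqtl_pairs: tuple = ()
    planted_or_proximal: float = 1.0
    planted_or_distal: float = 1.0
    enriched_terms: tuple = ()

    def merged(self, **kwargs) -> "SyntheticTruth":
        return replace(self, **kwargs)


def default_config(coupling: str = "independent", seed: int = 0,
                   n_domains: int = 6, n_loops: int = 6,
                   **overrides) -> SimulationConfig:
    """The standard synthetic chromosome: 2.56 Mb, ``n_domains`` contact
    domains separated by 10-kb gaps, ``n_loops`` focal loops anchored near
    domain starts two domains apart.

    Under ``independent`` the recombination hotspots are drawn at random
    positions; under ``boundary_coincident``/``anchor_ld`` one hotspot
    sits in the middle of every inter-domain gap, so LD blocks and contact
    domains coincide. Analyses probing sub-domain scales use a larger
    ``n_domains`` so planted structure exists at the interrogated scale.
    """
    rng = np.random.default_rng(seed + 101)
    chrom_length = overrides.pop("chrom_length", 2_560_000)
    bin_size = overrides.get("bin_size", 5000)
    edges = (np.linspace(0, chrom_length, n_domains + 1) // bin_size
             ).astype(int) * bin_size
    domains = tuple(
        (int(edges[k] + bin_size), int(edges[k + 1] - bin_size))
        for k in range(n_domains)
    )
    # loops spread evenly along the chromosome, two domains apart
    loops = []
    span = max(2, n_domains - 2)
    step = max(1, span // max(n_loops, 1))
    for k in range(n_loops):
        d1 = (k * step) % span
        d2 = d1 + 2
        off = bin_size * 3 * ((k * step) // span)  # stagger wrapped loops
        a = (domains[d1][0] + bin_size + off,
             domains[d1][0] + 2 * bin_size + off)
        b = (domains[d2][0] + bin_size + off,
             domains[d2][0] + 2 * bin_size + off)
        if b[1] < domains[d2][1] and (a, b) not in loops:
            loops.append((a, b))
    if coupling == "independent":
        # uniform over the whole chromosome: P(no hotspot between two
        # sites) then depends only on their separation, not position
        hotspots = tuple(sorted(set(
            int(p)
            for p in rng.integers(1, chrom_length,
                                  size=max(1, n_domains - 1))
        )))
    else:
        hotspots = tuple(int((domains[k][1] + domains[k + 1][0]) // 2)
                         for k in range(n_domains - 1))
    cfg = SimulationConfig(
        chrom_length=chrom_length,
        hotspot_positions=hotspots,
        domain_intervals=domains,
        loop_anchors=tuple(loops),
        coupling=coupling,
        seed=seed,
        **overrides,
    )
    return cfg


def _mosaic_founder_indices(
    rng: np.random.Generator,
    n_hap: int,
    positions: np.ndarray,
    hotspots: np.ndarray,
    bg_rate: float,
    hs_rate: float,
    k_founders: int,
) -> np.ndarray:
    """Founder index per haplotype per SNP under the mosaic model.

    A "switch" resamples the founder uniformly from all K founders (so it
    may land on the same founder: switch rate 1 decorrelates completely).
    """
    m = positions.size
    idx = np.empty((n_hap, m), dtype=np.int32)
    idx[:, 0] = rng.integers(0, k_founders, size=n_hap)
    # does a hotspot fall in (pos[k], pos[k+1]] ?
    rates = np.full(m - 1, bg_rate)
    if hotspots.size:
        lo = np.searchsorted(hotspots, positions[:-1], side="right")
        hi = np.searchsorted(hotspots, positions[1:], side="right")
        rates[hi > lo] = hs_rate
    switches = rng.random((n_hap, m - 1)) < rates[None, :]
    draws = rng.integers(0, k_founders, size=(n_hap, m - 1)).astype(np.int32)
    for k in range(1, m):
        idx[:, k] = np.where(switches[:, k - 1], draws[:, k - 1], idx[:, k - 1])
    return idx


def simulate_haplotypes(
    config: SimulationConfig,
) -> tuple[HaplotypePanel, SyntheticTruth]:
    """Founder-mosaic haplotype panel with planted hotspot LD breaks.

    SNPs with MAF below ``config.maf_floor`` are dropped after simulation.
    Under ``anchor_ld`` coupling a perfect-LD SNP pair is planted across
    each focal loop's two anchors.
    """
    if config.n_snps < 2:
        raise ValueError("n_snps must be at least 2")
    if config.founder_count < 2:
        raise ValueError("founder_count must be at least 2")
    rng = np.random.default_rng(config.seed)
    positions = np.sort(
        rng.choice(config.chrom_length - 1, size=config.n_snps, replace=False)
    ).astype(np.int64) + 1
    if config.coupling == "anchor_ld":
        # guarantee a SNP inside every loop anchor so the planted
        # perfect-LD pair exists
        free = np.ones(positions.size, dtype=bool)
        for (a, b) in config.loop_anchors:
            for (s, e) in (a, b):
                inside = (positions > s) & (positions <= e)
                if inside.any():
                    free[np.argmax(inside)] = False
                    continue
                movable = np.flatnonzero(free)
                k = movable[np.argmin(np.abs(positions[movable] - s))]
                taken = set(positions.tolist())
                cand = int(rng.integers(s + 1, e + 1))
                while cand in taken:
                    cand = int(rng.integers(s + 1, e + 1))
                positions[k] = cand
                free[k] = False
        positions = np.sort(positions)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("non-increasing SNP positions")
    founders = rng.integers(0, 2, size=(config.founder_count, config.n_snps),
                            dtype=np.uint8)
    hotspots = np.asarray(sorted(config.hotspot_positions), dtype=np.int64)
    idx = _mosaic_founder_indices(
        rng, config.n_haplotypes, positions, hotspots,
        config.background_switch_rate, config.hotspot_switch_rate,
        config.founder_count,
    )
    if config.coupling == "anchor_ld":
        # make the source site polymorphic among founders before copying
        for (a, b) in config.loop_anchors:
            ia = np.flatnonzero((positions > a[0]) & (positions <= a[1]))
            if ia.size:
                founders[:, ia[0]] = np.arange(config.founder_count) % 2
    alleles = founders[idx, np.arange(positions.size)[None, :]]
    if config.coupling == "anchor_ld":
        for (a, b) in config.loop_anchors:
            ia = np.flatnonzero((positions > a[0]) & (positions <= a[1]))
            ib = np.flatnonzero((positions > b[0]) & (positions <= b[1]))
            if ia.size and ib.size:
                alleles[:, ib[0]] = alleles[:, ia[0]]
    freq = alleles.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= config.maf_floor
    if not keep.any():
        raise ValueError("all SNPs fell below the MAF floor; degenerate config")
    panel = HaplotypePanel(alleles[:, keep], positions[keep], chrom=config.chrom)
    truth = SyntheticTruth(
        hotspot_positions=tuple(int(h) for h in hotspots),
        domain_boundaries=tuple(sorted(
            {int(c) for s, e in config.domain_intervals for c in (s, e)}
        )),
        loop_anchor_pairs=tuple(config.loop_anchors),
    )
    return panel, truth


def _bin_of(pos: np.ndarray | int, bin_size: int) -> np.ndarray | int:
    return np.asarray(pos) // bin_size


def _domain_bins(config: SimulationConfig) -> np.ndarray:
    """Domain id per bin (-1 outside any domain); bins assigned by their
    midpoint."""
    n_bins = config.chrom_length // config.bin_size
    mids = (np.arange(n_bins) + 0.5) * config.bin_size
    dom = np.full(n_bins, -1, dtype=np.int64)
    for d, (s, e) in enumerate(config.domain_intervals):
        dom[(mids >= s) & (mids < e)] = d
    return dom


def _loop_bin_pairs(config: SimulationConfig) -> list[tuple[int, int]]:
    out = []
    for (a, b) in config.loop_anchors:
        i = int(((a[0] + a[1]) // 2) // config.bin_size)
        j = int(((b[0] + b[1]) // 2) // config.bin_size)
        if i > j:
            i, j = j, i
        out.append((i, j))
    return out


def simulate_contact_map(
    config: SimulationConfig,
) -> tuple[ContactMatrix, SyntheticTruth]:
    """Poisson contact map with power-law decay, domain and loop boosts,
    and lognormal per-bin bias; expected total count equals ``depth``."""
    n_bins = config.chrom_length // config.bin_size
    if n_bins < 10:
        raise ValueError("need at least 10 bins")
    rng = np.random.default_rng(config.seed + 1)
    bias = (
        rng.lognormal(0.0, config.bias_sd, size=n_bins)
        if config.bias_sd > 0 else np.ones(n_bins)
    )
    i, j = np.triu_indices(n_bins)
    d = j - i
    rate = (d + 1.0) ** (-config.alpha)
    dom = _domain_bins(config)
    same = (dom[i] >= 0) & (dom[i] == dom[j])
    rate = np.where(same, rate * config.domain_boost, rate)
    loop_pairs = _loop_bin_pairs(config)
    if loop_pairs:
        li = np.array([p[0] for p in loop_pairs])
        lj = np.array([p[1] for p in loop_pairs])
        flat = i.astype(np.int64) * n_bins + j
        lflat = li.astype(np.int64) * n_bins + lj
        rate[np.isin(flat, lflat)] *= config.loop_boost
    rate = rate * bias[i] * bias[j]
    if not np.all(np.isfinite(rate)):
        raise ValueError("non-finite expected contact rate")
    rate *= config.depth / rate.sum()
    counts = rng.poisson(rate).astype(np.float64)
    nz = counts > 0
    matrix = ContactMatrix(
        bin_size=config.bin_size,
        n_bins=n_bins,
        chrom=config.chrom,
        bins_i=i[nz],
        bins_j=j[nz],
        values=counts[nz],
    )
    truth = SyntheticTruth(
        hotspot_positions=tuple(config.hotspot_positions),
        domain_boundaries=tuple(sorted(
            {int(c) for s, e in config.domain_intervals for c in (s, e)}
        )),
        loop_anchor_pairs=tuple(config.loop_anchors),
    )
    return matrix, truth


def simulate_interaction_calls(
    matrix: ContactMatrix,
    truth: SyntheticTruth,
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    min_bin_separation: int = 2,
    max_bin_separation: int | None = None,
    kind: str = "pchic",
) -> InteractionSet:
    """Interaction calls over the contact map's bins.

    Positives (score >= 5, drawn as 5 + Exponential) are anchored at the
    planted loops and then at the highest-O/E bin pairs; negatives
    (score < 5, uniform) at random remaining bin pairs.
    ``max_bin_separation`` restricts calls to short-range pairs, where
    single-count O/E outliers at sparse long-range diagonals would
    otherwise dominate the candidate list.
    """
    rng = np.random.default_rng(seed)
    bin_size = matrix.bin_size
    n_bins = matrix.n_bins
    if max_bin_separation is None:
        max_bin_separation = n_bins
    oe = observed_over_expected(vc_normalize(matrix))
    cand_order = np.argsort(-oe.values)
    pos_pairs: list[tuple[int, int]] = []
    for (a, b) in truth.loop_anchor_pairs:
        i = int(((a[0] + a[1]) // 2) // bin_size)
        j = int(((b[0] + b[1]) // 2) // bin_size)
        if i > j:
            i, j = j, i
        if j - i >= min_bin_separation and (i, j) not in pos_pairs:
            pos_pairs.append((i, j))
    for k in cand_order:
        if len(pos_pairs) >= n_pos:
            break
        pair = (int(oe.bins_i[k]), int(oe.bins_j[k]))
        sep = pair[1] - pair[0]
        if (min_bin_separation <= sep <= max_bin_separation
                and pair not in pos_pairs):
            pos_pairs.append(pair)
    pos_pairs = pos_pairs[:n_pos]
    if len(pos_pairs) < n_pos:
        raise ValueError("not enough candidate bin pairs for positives")
    taken = set(pos_pairs)
    max_avail = n_bins * (n_bins - 1) // 2
    if n_pos + n_neg > max_avail:
        raise ValueError("n_pos + n_neg exceeds available bin pairs")
    neg_pairs: list[tuple[int, int]] = []
    while len(neg_pairs) < n_neg:
        i = int(rng.integers(0, n_bins - min_bin_separation))
        j = int(rng.integers(i + min_bin_separation,
                             min(i + max_bin_separation + 1, n_bins)))
        if (i, j) not in taken:
            taken.add((i, j))
            neg_pairs.append((i, j))
    pos_scores = SCORE_THRESHOLD + rng.exponential(3.0, size=len(pos_pairs))
    neg_scores = rng.uniform(0.0, SCORE_THRESHOLD, size=len(neg_pairs))
    rows = []
    for (i, j), score in zip(pos_pairs + neg_pairs,
                             np.concatenate([pos_scores, neg_scores])):
        rows.append({
            "chrom": matrix.chrom,
            "start1": i * bin_size, "end1": (i + 1) * bin_size,
            "start2": j * bin_size, "end2": (j + 1) * bin_size,
            "score": float(score),
            "significant": bool(score >= SCORE_THRESHOLD),
            "kind": kind,
        })
    return InteractionSet(pd.DataFrame(rows))


def random_interactions(
    n: int,
    chrom_length: int,
    frac_significant: float = 0.5,
    anchor_size: int = 5000,
    min_dist: int = 10_000,
    max_dist: int = 2_000_000,
    seed: int = 0,
    chrom: str = "chr1",
    kind: str = "pchic",
) -> InteractionSet:
    """Population of interaction records with log-uniform distances, used
    by the enrichment fixtures where no contact map is needed."""
    rng = np.random.default_rng(seed)
    dist = np.exp(rng.uniform(np.log(min_dist), np.log(max_dist), size=n))
    start1 = rng.integers(0, chrom_length - max_dist - 2 * anchor_size, size=n)
    start2 = (start1 + dist).astype(np.int64)
    sig = rng.random(n) < frac_significant
    score = np.where(sig,
                     SCORE_THRESHOLD + rng.exponential(3.0, size=n),
                     rng.uniform(0, SCORE_THRESHOLD, size=n))
    df = pd.DataFrame({
        "chrom": chrom,
        "start1": start1, "end1": start1 + anchor_size,
        "start2": start2, "end2": start2 + anchor_size,
        "score": score, "significant": sig, "kind": kind,
    })
    return InteractionSet(df)


def make_gene_annotation(
    interactions: InteractionSet,
    promoter_halfwidth: int = 1000,
    prefix: str = "G",
) -> GeneAnnotation:
    """One gene per distinct bait fragment: TSS at the bait midpoint,
    promoter a +/- ``promoter_halfwidth`` window around it."""
    baits = (
        interactions.df[["start1", "end1"]]
        .drop_duplicates()
        .sort_values(["start1", "end1"])
        .reset_index(drop=True)
    )
    width = max(2, int(np.ceil(np.log10(max(len(baits), 2)))))
    rows = []
    for k, r in baits.iterrows():
        tss = int((r.start1 + r.end1) // 2)
        rows.append({
            "gene_id": f"{prefix}{k:0{width}d}",
            "tss": tss,
            "promoter_start": tss - promoter_halfwidth,
            "promoter_end": tss + promoter_halfwidth,
            "bait_start": int(r.start1),
            "bait_end": int(r.end1),
        })
    return GeneAnnotation(pd.DataFrame(rows))


def simulate_regulatory_fixtures(
    interactions: InteractionSet,
    annotation: GeneAnnotation,
    or_proximal: float = 20.0,
    or_distal: float = 4.0,
    base_rate: float = 0.02,
    seed: int = 0,
    proximal_cutoff: int = 200_000,
    n_background_terms: int = 29,
    term_rate: float = 0.10,
    n_gwas_interactions: int = 40,
) -> tuple[pd.DataFrame, pd.DataFrame, GOAnnotation, SyntheticTruth]:
    """Plant eQTLs, GWAS SNPs and GO annotations on an interaction set.

    Each interaction emits an eQTL (SNP uniform in the PIR, target = bait
    gene) with probability base_rate*OR/(1-base_rate+base_rate*OR) if
    significant, and base_rate otherwise, where OR is ``or_proximal``
    below ``proximal_cutoff`` and ``or_distal`` beyond it. One GO term is
    planted to cover exactly the bait genes of the phenotype's SNP-bearing
    significant interactions; a second phenotype gets random SNPs as a
    null.
    """
    if len(annotation) < 20:
        raise ValueError("annotation must contain at least 20 genes")
    if or_proximal < 1 or or_distal < 1:
        raise ValueError("planted odds ratios must be >= 1")
    for orr in (or_proximal, or_distal):
        q = base_rate * orr / (1 - base_rate + base_rate * orr)
        if q >= 1:
            raise ValueError("base_rate * OR implies probability >= 1")
    rng = np.random.default_rng(seed)
    df = interactions.df
    gene_of_bait = {
        (int(r.bait_start), int(r.bait_end)): str(r.gene_id)
        for r in annotation.df.itertuples()
        if not (pd.isna(r.bait_start) or pd.isna(r.bait_end))
    }
    orr = np.where(df["distance"].to_numpy() < proximal_cutoff,
                   or_proximal, or_distal)
    q_sig = base_rate * orr / (1 - base_rate + base_rate * orr)
    prob = np.where(df["significant"].to_numpy(), q_sig, base_rate)
    emits = rng.random(len(df)) < prob
    eqtl_rows = []
    for k in np.flatnonzero(emits):
        r = df.iloc[k]
        gene = gene_of_bait.get((int(r["start1"]), int(r["end1"])))
        if gene is None:
            continue
        snp = int(rng.integers(r["start2"] + 1, r["end2"] + 1))  # 1-based
        eqtl_rows.append({"snp_pos": snp, "gene_id": gene})
    eqtls = pd.DataFrame(eqtl_rows, columns=["snp_pos", "gene_id"])

    # GWAS: planted phenotype SNPs in PIRs of sampled significant records
    sig_idx = np.flatnonzero(df["significant"].to_numpy())
    take = rng.choice(sig_idx, size=min(n_gwas_interactions, sig_idx.size),
                      replace=False)
    gwas_rows = []
    planted_genes: set[str] = set()
    for k in take:
        r = df.iloc[k]
        snp = int(rng.integers(r["start2"] + 1, r["end2"] + 1))
        gwas_rows.append({"phenotype": "planted_pheno", "snp_pos": snp})
        gene = gene_of_bait.get((int(r["start1"]), int(r["end1"])))
        if gene is not None:
            planted_genes.add(gene)
    chrom_end = int(df[["end1", "end2"]].to_numpy().max())
    for _ in range(len(take)):
        gwas_rows.append({
            "phenotype": "null_pheno",
            "snp_pos": int(rng.integers(1, chrom_end + 1)),
        })
    gwas = pd.DataFrame(gwas_rows, columns=["phenotype", "snp_pos"])

    # GO: random background terms plus the planted term
    genes = annotation.df["gene_id"].astype(str).tolist()
    terms = [f"GO:{k:07d}" for k in range(1, n_background_terms + 1)]
    planted_term = "GO:9999999"
    mapping: dict[str, set[str]] = {g: set() for g in genes}
    for t in terms:
        members = rng.random(len(genes)) < term_rate
        for g, m in zip(genes, members):
            if m:
                mapping[g].add(t)
    for g in planted_genes:
        mapping[g].add(planted_term)
    go = GOAnnotation(mapping)

    truth = SyntheticTruth(
        eqtl_pairs=tuple((int(r["snp_pos"]), str(r["gene_id"]))
                         for _, r in eqtls.iterrows()),
        planted_or_proximal=float(or_proximal),
        planted_or_distal=float(or_distal),
        enriched_terms=(("planted_pheno", planted_term),),
    )
    return eqtls, gwas, go, truth
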