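"""End-to-end synthetic pipeline driver.

Runs simulate -> LD scan/blocks -> contact normalization/O-E ->
concordance, interaction-level LD, boundary permutation test and eQTL/GO
enrichment on one synthetic chromosome, writing TSV result tables and a
JSON run manifest. Deterministic given (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boundaries import BoundarySet, boundary_permutation_test
from .concordance import build_bin_pair_track, concordance_by_window, decay_profile
from .enrichment import (bh_adjust, go_enrichment_compare,
                         interaction_feature_vectors, quantile_distance_bins,
                         stratified_or)
from .hic import expected_by_distance, observed_over_expected, vc_normalize
from .interactions import interaction_ld_log_ratio, shuffle_same_chrom
from .io import (write_bed_blocks, write_bedpe, write_ld_pairs,
                 write_triplet_matrix, write_truth, write_vcf_panel)
from .ld import call_ld_blocks, pairwise_ld_scan
from .synthetic import (SimulationConfig, default_config, make_gene_annotation,
                        simulate_contact_map, simulate_haplotypes,
                        simulate_interaction_calls, simulate_regulatory_fixtures)

log = logging.getLogger(__name__)


def run_pipeline(outdir, config: SimulationConfig | None = None,
                 seed: int = 0, n_pos: int = 80, n_neg: int = 80,
                 write_inputs: bool = False) -> dict:
    """Execute the full synthetic analysis; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = default_config("boundary_coincident", seed=seed,
                                n_domains=24, n_loops=20, n_snps=1024)
    else:
        config = SimulationConfig(**{**asdict(config), "seed": seed})

    log.info("simulating haplotypes and contact map")
    panel, truth = simulate_haplotypes(config)
    matrix, truth_cm = simulate_contact_map(config)
    truth = truth.merged(loop_anchor_pairs=truth_cm.loop_anchor_pairs)
    if write_inputs:
        write_vcf_panel(panel, outdir / "panel.vcf", outdir / "panel.tsv")
        write_triplet_matrix(matrix, outdir / "contacts.tsv")

    log.info("LD scan and block calling")
    pairs = pairwise_ld_scan(panel)
    blocks = call_ld_blocks(panel)
    write_ld_pairs(pairs, outdir / "ld_pairs.tsv")
    write_bed_blocks(blocks, outdir / "ld_blocks.bed")

    log.info("contact normalization and O/E")
    norm = vc_normalize(matrix)
    expected_by_distance(norm)
    oe = observed_over_expected(norm)
    write_triplet_matrix(oe, outdir / "contact_oe.tsv")

    log.info("multi-scale concordance and decay profiles")
    track = build_bin_pair_track(pairs, oe, bin_size=config.bin_size,
                                 snp_positions=panel.positions)
    conc = concordance_by_window(track)
    conc.to_csv(outdir / "concordance.tsv", sep="\t", index=False,
                float_format="%.6g")
    profile, rho = decay_profile(pairs, norm)
    profile.to_csv(outdir / "decay_profile.tsv", sep="\t", index=False,
                   float_format="%.6g")

    log.info("interaction-level LD")
    calls = simulate_interaction_calls(matrix, truth, n_pos=n_pos,
                                       n_neg=n_neg, seed=seed + 2)
    write_bedpe(calls, outdir / "interactions.bedpe")
    positives = calls.significant
    matched = shuffle_same_chrom(positives, config.chrom_length,
                                 seed=seed + 3, avoid=positives)
    ild = interaction_ld_log_ratio(positives, matched, pairs,
                                   panel.positions, seed=seed + 4)
    pd.DataFrame([ild]).to_csv(outdir / "interaction_ld.tsv", sep="\t",
                               index=False, float_format="%.6g")

    log.info("boundary permutation test")
    domains = BoundarySet.from_intervals(config.domain_intervals,
                                         chrom=config.chrom)
    btest = boundary_permutation_test(domains, blocks, config.chrom_length,
                                      alternative="shorter", seed=seed + 5)
    null_q = np.percentile(btest["null_medians"], [5, 25, 50, 75, 95])
    pd.DataFrame([{
        "observed_median": btest["observed_median"],
        "null_q05": null_q[0], "null_q25": null_q[1], "null_q50": null_q[2],
        "null_q75": null_q[3], "null_q95": null_q[4],
        "alternative": btest["alternative"], "p": btest["p"],
    }]).to_csv(outdir / "boundary_test.tsv", sep="\t", index=False,
               float_format="%.6g")

    log.info("eQTL and GO enrichment")
    annotation = make_gene_annotation(calls)
    eqtls, gwas, go, truth_reg = simulate_regulatory_fixtures(
        calls, annotation, seed=seed + 6)
    truth = truth.merged(
        eqtl_pairs=truth_reg.eqtl_pairs,
        planted_or_proximal=truth_reg.planted_or_proximal,
        planted_or_distal=truth_reg.planted_or_distal,
        enriched_terms=truth_reg.enriched_terms,
    )
    feats = interaction_feature_vectors(calls, eqtls, annotation, pairs,
                                        panel.positions)
    n_bins = max(2, min(4, len(feats) // 20))
    labels, keep = quantile_distance_bins(calls, n_bins=n_bins)
    res = stratified_or(feats["has_eqtl"].to_numpy()[keep],
                        feats["significant"].to_numpy()[keep], labels)
    eq_rows = [vars(r) for r in res]
    eq_df = pd.DataFrame(eq_rows)
    eq_df["q"] = bh_adjust(eq_df["p"].fillna(1.0))
    eq_df.to_csv(outdir / "enrichment_eqtl.tsv", sep="\t", index=False,
                 float_format="%.6g")
    gwas_map = {p: g["snp_pos"].to_numpy()
                for p, g in gwas.groupby("phenotype")}
    go_res, go_counts = go_enrichment_compare(
        gwas_map, annotation, go, blocks=blocks, interactions=calls)
    go_res.to_csv(outdir / "go_enrichment.tsv", sep="\t", index=False,
                  float_format="%.6g")
    go_counts.to_csv(outdir / "go_counts.tsv", sep="\t", index=False,
                     float_format="%.6g")
    write_truth(truth, outdir / "truth.json")

    param_blob = json.dumps(asdict(config), sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(param_blob.encode()).hexdigest()[:16],
        "tables": sorted(p.name for p in outdir.glob("*.tsv"))
        + ["ld_blocks.bed", "interactions.bedpe", "truth.json"],
        "spearman_rho": rho,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
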