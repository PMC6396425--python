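"""Write one synthetic fixture set per coupling scenario.

Produces, under results/fixtures/<coupling>/, a phased VCF + panel TSV,
a triplet contact matrix, domain BED and the planted-truth JSON. These are
the standard-format views of the simulated chromosome that every later
step could equally read back from disk.
"""

from pathlib import Path

from ldhic import io as ldio
from ldhic.experiments import loop_scale_config
from ldhic.synthetic import simulate_contact_map, simulate_haplotypes

SEED = 1
OUT = Path("results/fixtures")

for coupling in ("independent", "boundary_coincident", "anchor_ld"):
    out = OUT / coupling
    out.mkdir(parents=True, exist_ok=True)
    cfg = loop_scale_config(coupling, SEED)
    panel, truth = simulate_haplotypes(cfg)
    matrix, _ = simulate_contact_map(cfg)
    ldio.write_vcf_panel(panel, out / "panel.vcf", out / "panel.tsv")
    ldio.write_triplet_matrix(matrix, out / "contacts.tsv")
    ldio.write_bed(cfg.domain_intervals, out / "domains.bed", chrom=cfg.chrom)
    ldio.write_truth(truth, out / "truth.json")
    print(f"{coupling}: {panel.n_snps} SNPs x {panel.n_haplotypes} "
          f"haplotypes, {matrix.n_bins} bins, "
          f"{len(cfg.loop_anchors)} loops -> {out}")
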