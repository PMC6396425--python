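# ldhic — linkage disequilibrium versus chromatin-interaction maps

Population-genetic association (LD) and physical chromatin contact are
both pairwise, distance-decaying structures on the genome, and noncoding
GWAS variants are routinely mapped to genes through either one. This
package implements, as a tested and reusable pipeline, the genome-scale
comparison of the two maps: pairwise r²/D′ and Gabriel-style haplotype
blocks from phased genotypes; vanilla-coverage normalization and
observed/expected (O/E) transforms of binned contact matrices;
multi-scale concordance of strong LD (r² > 0.8) with frequent contacts
(top quartile); interaction-level LD log ratios against distance-matched
nulls; permutation tests on domain-versus-block boundaries; and
eQTL/GO-term enrichment contrasts between three SNP-to-gene mapping
strategies (closest gene, same LD block, promoter-capture interaction).

The statistics at the core, for haplotype counts at two bi-allelic loci:

    D  = p_AB − p_A p_B
    r² = D² / (p_A(1−p_A) p_B(1−p_B))        D′ = |D| / D_max

with Gabriel block calling from likelihood-grid confidence intervals on
|D′| (strong LD: ci_low ≥ 0.70 and ci_high ≥ 0.98), O/E contact values
`oe_ij = m_ij / expected(|i−j|)`, and 2×2 enrichment odds ratios with
Wald CIs and Benjamini–Hochberg control.

Real inputs of this kind (1000-Genomes-scale panels, deep Hi-C, PCHi-C
score tables) are too large to ship, so the package carries a first-class
synthetic-data module: a founder-mosaic haplotype model with planted
recombination hotspots, Poisson contact maps with power-law decay plus
domain/loop boosts, score-thresholded interaction calls, and regulatory
fixtures with planted eQTL odds ratios and one enriched GO term. Every
analysis is validated by recovering what the generator planted, under
three couplings: `independent`, `boundary_coincident` (hotspots on domain
boundaries) and `anchor_ld` (perfect-LD SNP pairs across loop anchors).
See `docs/methods.md` for the model and its limits.

## Layout

- `src/ldhic/` — the library: `ld` (r²/D′, EM, D′ CIs, block calling),
  `hic` (VC, expected, O/E), `concordance`, `interactions`, `boundaries`,
  `enrichment`, `synthetic` (generators), `experiments` (the study
  conditions), `io`, `pipeline`, `cli`.
- `analysis/01…07_*.py` — numbered drivers that run each analysis and
  write tables under `results/`.
- `scripts/acceptance.py` — recomputes every headline quantity from
  scratch (below).

## Worked example

```bash
python analysis/01_simulate_fixtures.py   # write VCF/contacts fixtures
python analysis/02_ld_blocks.py
python analysis/04_concordance.py
```

prints, for the LD step,

```
145339 stored LD pairs; 43 blocks, median length 49928 bp
hotspot recovery over 20 seeds: 99/99 (100.0%) of planted hotspots lie
within one inter-SNP gap of a called block edge
```

— the block caller places an edge at essentially every planted
recombination hotspot — and, for the concordance step,

```
independent: mean observed-expected per window
     10 kb: -0.0036
     20 kb: -0.0029
     40 kb: -0.0036
     ...
boundary_coincident: mean observed-expected per window
     10 kb: +0.0210
     20 kb: +0.0401
     40 kb: +0.0554
```

— when LD blocks and contact domains are unrelated, strong LD and
frequent contacts co-occur exactly as often as the distance-matched
independence expectation predicts (differences are Monte-Carlo noise
around 0); when hotspots sit on domain boundaries the co-occurrence
exceeds it at every informative window size. The equivalent contrast for
focal interactions (`analysis/05_interaction_ld.py`) gives a log ratio of
mean cross-anchor max r² near 0 under independence and ≈ +3.2 with
planted anchor LD, and the enrichment step (`analysis/07_enrichment.py`)
recovers the planted proximal/distal eQTL odds ratios of 20 and 4 (log
OR ≈ 3.0 and 1.4) inside their 95% CIs.

A single end-to-end run over one simulated chromosome, emitting all
result tables plus a run manifest, is

```bash
ldhic run --outdir results/run1 --seed 7
```

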