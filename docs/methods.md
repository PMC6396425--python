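# Methods

`ldhic` compares the genetic architecture of a chromosome (linkage
disequilibrium, LD) with its physical architecture (chromatin contacts).
Because the real inputs — phased genotype panels, deeply sequenced Hi-C
maps, promoter-capture interaction calls, eQTL and GWAS tables — are
large external resources, every analysis here runs on synthetic
chromosomes whose generative model plants the structure the analyses are
supposed to find. The planted truth is machine-readable, so each method is
validated by recovery, not by eyeballing.

## Pairwise LD

For two bi-allelic loci with haplotype frequencies `p_AB` and allele
frequencies `p_A`, `p_B`:

    D  = p_AB − p_A p_B
    r² = D² / (p_A(1−p_A) p_B(1−p_B))
    D′ = |D| / D_max,  D_max = min(p_A(1−p_B), (1−p_A)p_B)   if D > 0
                       D_max = min(p_A p_B, (1−p_A)(1−p_B))  if D ≤ 0

Both statistics are clipped to [0, 1] against floating-point rounding.
Monomorphic loci are rejected; callers filter by minor-allele frequency
(MAF ≥ 0.05 by default) first. The windowed scan stores pairs within 2 Mb
and drops records with r² < 0.01 from storage; downstream consumers treat
unstored pairs as r² = 0. Phased input is the primary path; unphased 3×3
genotype tables route through a standard two-locus EM in which only double
heterozygotes are phase-ambiguous. The all-0.25 table is a symmetric fixed
point of that EM (both phases equally likely); it is documented as a
degenerate case rather than "fixed".

## D′ confidence intervals and haplotype blocks

The |D′| confidence interval fixes the allele frequencies at their MLEs
and the sign of D at its point estimate, evaluates the multinomial
likelihood on a |D′| grid over [0, 1] (step 0.001), normalizes it to unit
mass, and reads off the 5% lower and upper tail bounds — the construction
popularized by Haploview. Block calling classifies each SNP pair within
2 Mb: *strong LD* if `ci_low ≥ 0.70` and `ci_high ≥ 0.98`, *strong
recombination* if `ci_high < 0.90`, else uninformative. A candidate block
(i..j) needs a strong-LD outermost pair and at least 95% strong pairs
among its informative pairs; candidates are accepted greedily by bp span
descending, ties broken by leftmost start, overlaps skipped — the output
is deterministic. Small-span block caps are disabled. The grid evaluation
is the computational hot spot and is implemented as a compiled kernel; a
pure-Python fallback with identical semantics exists, and the kernel is
asserted against the scalar implementation to 1e-9.

## Contact matrices

Matrices are sparse upper-triangular triplets at 5-kb resolution.
Vanilla-coverage (VC) normalization divides each entry by the product of
its two bins' symmetric coverage marginals and rescales so total
normalized mass equals total raw mass; zero-marginal bins are excluded
(not smoothed) and drop from all statistics. VC is recomputed from the
matrix rather than read from pre-supplied coefficient vectors — a
deliberate substitution, since the synthetic maps carry their own biases.
Note VC is one balancing half-step: it is idempotent (up to a global
scale) exactly on bias-factorizable matrices, which is the generative
model here, but not on arbitrary matrices.

Expected-by-distance is the mean normalized value per diagonal over all
included bin pairs, structural zeros counted (a nonzero-only variant is a
flag). O/E divides each entry by the expected value at its distance;
entries at distances with zero expected, or touching excluded bins, are
undefined and omitted. By construction the per-diagonal O/E mean over
included pairs is exactly 1, which the tests assert to 1e-12.

## Multi-scale concordance

Each 5-kb bin pair receives an LD summary — the 75th percentile of r²
over SNP pairs spanning the two bins, below-floor pairs entering as 0 —
and a contact value (O/E by default; distance correction matters, see
below). For each window size w in {5, 10, 20, 40, 80, 160, 320, 640,
1280} kb the chromosome is partitioned into consecutive non-overlapping
windows; bin pairs with both bins in one window are collected, flagged
*strong LD* (summary > 0.8) and *frequent contact* (above the 75th
percentile of the collected contact values — one threshold per
window-size analysis), and concordance is the fraction carrying both
flags. Note the 5-kb window cannot contain two distinct 5-kb bins, so
that row is always empty; it is reported with n = 0.

Three independence expectations are available. The plain product of
marginals (default) is the naive reference, but both masks decay with
genomic distance, so it carries a confounding bias even when LD and
contacts are unrelated. The *distance-matched* expectation multiplies the
marginals within each bin-separation stratum and averages over strata; it
is the analytic expectation of the third option, explicitly shuffling the
contact mask across bin pairs at fixed distance. The null-calibration
experiments use the distance-matched form, since only a
distance-respecting expectation can be unbiased under the generator's
independence scenario; the coupled-scenario excess is detected under the
same form.

## Interaction-level LD

SNPs are assigned to interaction anchors by half-open interval membership
(anchors 0-based half-open, SNPs 1-based points). Each interaction's LD
is the maximum stored r² over cross-anchor SNP pairs; interactions with a
SNP-less anchor contribute 0 by default (a drop flag exists — the
alternative is defensible and exposed). The headline statistic is the
natural-log ratio of mean per-interaction max LD, significant versus
non-significant, with a 95% bootstrap CI over interactions (1000
resamples, seeded). Negatives must be distance-matched, because max LD
depends strongly on anchor separation: either joint-shift shuffling
(both anchors moved rigidly to a uniform position on the same chromosome,
preserving separation exactly, redrawing placements that hit a positive
anchor) or quantile binning of candidate distances (20 bins by default,
per-bin sampling without replacement). Promoter-capture-style records use
score ≥ 5 as the significance convention.

## Boundary statistics

Domains and blocks are reduced to point boundaries (both edges each).
The test statistic is the median distance from each domain boundary to
its nearest block boundary. The null redraws block locations uniformly
without overlap, preserving the multiset of block lengths, via the
uniform-spacings construction (the free space is split by sorted uniform
draws), which samples the uniform non-overlapping placement distribution
exactly in O(n) with no rejection loop; block order is randomized per
draw. p = (1 + #extreme) / (n_perm + 1) with a configurable one-sided
direction, so p > 0 always. A 1600-dataset self-calibration puts
P(p ≤ α) within ±0.02 of α at α ∈ {0.01, 0.05, 0.10}; 1600 datasets are
used (rather than a few hundred) so the ±0.02 band corresponds to ≈2.7
binomial standard errors and the check has real power. A gap-preserving
circular-rotation permutation is available as an option.

## Enrichment

The eQTL contrast crosses "interaction is significant" with "interaction
carries an eQTL" (SNP in the promoter-interacting region and target gene
on the bait) within distance strata (quantile bins up to 2 Mb, or an
explicit proximal/distal split at 200 kb for the recovery experiments).
Per stratum the odds ratio is `ad/bc` with the Haldane–Anscombe 0.5
correction when a cell is zero, a Wald CI on the log OR, and a Wald p.
With a single binary covariate this equals the logistic-regression
estimate; the equivalence is asserted in the tests against an IRLS
reference fitted there. GO enrichment uses two-sided Fisher exact tests —
for the interaction strategy the unit is the significant interaction
(phenotype SNP in PIR × bait gene has term); for the closest-gene and
same-LD-block strategies the unit is the gene — with Benjamini–Hochberg
control applied within each phenotype × strategy family across terms
(a global-family option exists). Closest-gene ties break lexicographically
by gene id.

## The synthetic generator

*Haplotypes.* A founder mosaic: K founders (default 2) with i.i.d.
Bernoulli(0.5) alleles; each haplotype copies a founder and, between
consecutive SNPs, resamples its founder uniformly with probability
`background_switch_rate` (5e-4) or `hotspot_switch_rate` (0.5) when a
planted hotspot lies in the interval. Resampling may land on the same
founder, so switch probability 1 decorrelates completely. With two
founders every polymorphic pair inside a founder-conserved segment has
r² ≈ 1 and D′ ≈ 1 — matching the empirical signature of haplotype blocks —
while a hotspot crossed at rate 0.5 leaves r² ≈ 0.25 and D′ ≈ 0.5 across
it, which the block classifier reads as strong recombination. SNPs below
the 5% MAF floor are dropped after simulation (with two founders roughly
half the sites are monomorphic and fall out, which the site counts below
anticipate). This model gives direct, local control of block boundaries
at O(n_hap · n_snps) cost; it makes no attempt at realistic genealogies,
demography, allele-frequency spectra or mutation processes.

*Contacts.* Poisson counts around `depth · b_i b_j (|i−j|+1)^(−α) ·
domain_boost^[same domain] · loop_boost^[loop pair]` with α = 1,
domain boost 2, loop boost 5, lognormal bin bias (σ = 0.3), total
expected count 2e6 over a 2.56-Mb chromosome at 5-kb bins. No
overdispersion, no translocations, no trans contacts.

*Calls.* Positives are planted loops plus highest-O/E bin pairs with
scores 5 + Exp(3); negatives are random bin pairs with scores U(0, 5);
significance is exactly score ≥ 5. An optional separation cap excludes
sparse long-range diagonals where single-count O/E outliers would
dominate the candidate list.

*Regulatory fixtures.* Each interaction emits an eQTL (SNP uniform in the
PIR, target = bait gene) with probability `b·OR/(1−b+b·OR)` if
significant and `b = 0.02` otherwise, OR = 20 below 200 kb and 4 beyond —
so the planted OR is exactly the odds ratio of the emission flags. One GO
term is planted on the bait genes of one phenotype's SNP-bearing
significant interactions over a background of 29 random terms (each gene
carrying each with probability 0.1); a second phenotype receives random
SNP positions as a built-in null.

*Couplings.* `independent` draws hotspots uniformly over the whole
chromosome, so the probability that no hotspot separates two sites
depends only on their separation — any positional profile would leak into
the concordance null. Loops are likewise spread evenly along the
chromosome. `boundary_coincident` puts one hotspot in the middle of every
inter-domain gap; `anchor_ld` additionally forces a SNP into each loop
anchor and copies the alleles across the pair (r² = 1), making the source
site polymorphic among founders first.

## Experiment scales

The recovery experiments fix their scenario geometry in
`ldhic.experiments`:

- *fine scale* (concordance): 80 domains of ≈22 kb on 2.56 Mb, 2048
  simulated SNPs (≈1 kept SNP per 2.5 kb — a thinning of 1000-Genomes
  common-variant density), 2000 haplotypes. The smallest analysis windows
  (10–40 kb) interrogate sub-domain scale, so the planted structure must
  exist there; with ≈300-kb domains the small windows see homogeneous
  signal and no method could recover the coupling.
- *loop scale* (interaction LD): 24 domains, 20 loops two domains apart.
- *block scale* (block recovery): 1.28 Mb, 220 simulated SNPs, hotspot
  switch probability 0.5, 50 seeds; recovery means a called block edge
  within one inter-SNP gap of the planted hotspot.

Monte-Carlo sweeps use 100 seeds (1600 datasets for the p-value
calibration); the reproduction script defaults to 30 seeds per sweep.
These sizes make the whole suite a desk-scale computation while leaving
the binomial noise on every reported rate well inside the bands the tests
assert.

## What passing these tests does and does not show

Recovery on planted truth demonstrates that the statistics, nulls and
calibrations are implemented correctly — not that real genomes behave
like the generator. In particular: the mosaic model has a two-point
allele-frequency spectrum and deterministic block interiors; Poisson
contacts lack the overdispersion real Hi-C shows; interaction scores
carry no distance-dependent background; and the GO fixture has no term
hierarchy, so the BH family-dependence question that a real GO graph
raises is out of scope by construction. Multi-chromosome genomes, sex
chromosomes, trans contacts and imputation are non-goals throughout.
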