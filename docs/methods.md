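# Methods

## Study design being modeled

The pipeline models a two-group, single-channel expression-array comparison:
brainstem RNA from two inbred mouse strains (DBA/1-like "treatment" vs
C57BL/6-like "control"), four arrays per group, measuring both coding mRNAs
and lncRNAs at transcript-level probes. Downstream questions are (i) which
transcripts are differentially expressed, (ii) where DE lncRNAs sit relative
to coding genes, (iii) whether cis-paired lncRNA/mRNA changes share
direction, (iv) which gene sets the DE mRNAs over-represent, and (v) whether
an independent qPCR cohort reproduces the array directions.

## Normalization

Quantile normalization is applied to raw linear intensities, exactly as the
rank-mean procedure states: per column, sort ascending; across columns, take
the mean at each rank; substitute; restore the input order. Log2 transform
happens afterwards, only for testing and clustering. Two numerical choices:

* **Ties.** Tied values within a column receive the mean of the rank-means
  of their tied positions. This makes the output invariant to the arbitrary
  sort order among ties and makes the transform idempotent. A consequence is
  that a column containing ties no longer carries the exact rank-mean
  multiset; on continuous intensity data ties have probability zero.
* **Scale.** Normalizing on the linear scale follows the procedure's
  reference to original values; because ranks are preserved by monotone
  transforms, the induced ordering is identical to log-scale normalization.

## Differential expression

Fold change is the ratio of group arithmetic means of normalized linear
intensities, reported ≥ 1 with an up/down label (equal means: "up" by fixed
convention). P values come from a Welch unequal-variance t-test on log2
intensities — the test itself is not specified by the study, and Welch is
the safe default for small two-group designs; rows with zero variance in
both groups are assigned p = 1 (equal means) or p = 0 (different means).
BH step-up FDR is computed separately for lncRNAs and mRNAs, because the two
classes are reported as separate result sets; joint correction is available
(`fdr_family="joint"`). Filters: primary FC ≥ 2 & P < 0.05; sensitivity
FC ≥ 2 & FDR < 0.05. All thresholds are parameters with these defaults.

## Positional classification

Coordinates are 0-based half-open internally; GTF I/O is 1-based inclusive,
BED12 0-based half-open. The six categories are evaluated per lncRNA against
all coding transcripts on its chromosome (interval-tree indexed, padded by
the bidirectional window):

1. sense_overlapping — same strand, lncRNA exon ∩ coding exon > 0;
2. intronic — same strand, lncRNA exon ∩ coding intron > 0 (and no exon
   overlap);
3. natural_antisense — opposite strand, exon ∩ exon > 0;
4. nonoverlapping_antisense — opposite strand, gene-body overlap, no exon
   overlap;
5. bidirectional — opposite strands, disjoint bodies, divergent (the
   plus-strand transcript entirely downstream of the minus-strand one), 5′
   ends < 1000 bp apart; for divergent disjoint transcripts the 5′-end gap
   equals the body gap;
6. intergenic — none of the above.

Where several definitions match, the first in the order above wins (it
orders by strength of physical overlap). Among multiple qualifying partners
the largest overlap (smallest 5′ gap for bidirectional) is reported, ties
broken by lexicographic transcript id. The exon-level reading of "antisense
overlap" keeps categories 3 and 4 disjoint; this is a deliberate
interpretation, not the only possible one.

A note on symmetry: the four overlap categories are invariant under flipping
every strand in the annotation, but the bidirectional relation is not — a
global flip turns divergent (head-to-head) geometry into convergent
(tail-to-tail), so bidirectional and intergenic assignments can legitimately
exchange under that transformation. The property tests assert exactly this.

## Cis coexpression pairing

Antisense pairs join each DE lncRNA in an antisense category with its DE
coding partner (distance 0). A nonoverlapping-antisense lncRNA lying wholly
inside its partner's gene body is labeled `intronic_antisense`, matching the
labels used in the published pair table. lincRNA pairs are built for each DE
intergenic lncRNA by taking the nearest DE coding gene on each genomic side
within 300 kb, so one lincRNA contributes up to two pairs. Distance is the
boundary gap between nearest transcript edges (TSS-to-TSS is a config
alternative the study does not disambiguate); upstream/downstream labels are
strand-relative for the lincRNA, and the convention is recorded in the
output. Pair membership requires passing the primary filter, because the
published counts refer to differentially expressed transcripts.

Concordance summaries count the four direction patterns and report exact
`fractions.Fraction` values, so the four fractions sum to exactly 1 and
frac(concordant) ≡ frac(up/up) + frac(down/down) — the identity behind the
published 12.9% + 55.6% = 68.5%.

## Over-representation

One-sided hypergeometric upper tails, P(X ≥ k) for k hits of an n-gene DE
list against a K-gene set in an N-gene universe, with BH correction across
sets and the enrichment score (k/n)/(K/N). The universe is the measured
transcript set (array-conditioned), not the genome. Up- and downregulated
lists are tested separately. No GO/KEGG topology or term databases are
bundled; collections come from GMT files (or the synthetic generator).

## qPCR relative quantification

Technical replicates are averaged per sample and gene before
ΔCt = Ct(target) − Ct(reference). Per-sample linear values 2^−ΔCt are
divided by the control-group arithmetic mean, which fixes the control mean
at exactly 1 (the classical 2^−ΔΔCt with group-mean centering coincides with
this at zero noise but leaves the control mean above 1 under noise, by
Jensen's inequality — the division is the contract the "control = 1"
convention actually states). Amplification efficiency is fixed at 2.0.
Per-sample additive Ct shifts cancel by construction.

## Synthetic data generator

What it emulates: log-normal probe intensities (Gaussian on log2 around a
baseline of 8, per-transcript baselines with SD 1.5, well noise
`noise_sd` = 0.25 log2 units by default), planted shifts of
±`planted_log2fc` (default 2, i.e. 4-fold) in the treatment group, 4 samples
per group, and a toy genome of 1 Mb "unit blocks": each planted lncRNA
shares its block only with its designed partner coding gene, intergenic
plants sit mid-block > 300 kb from all coding genes, and lincRNA-pair plants
carry exactly one coding neighbor at a planted gap drawn from 5–250 kb.
Background coding genes (3 exons, 5–20 kb) and lncRNAs (0.3–5 kb,
log-uniform) are packed at ≥ 20 kb spacing, which rules out accidental
overlap or bidirectional geometry. Planted concordant pairs are allocated in
exact counts (round(fraction × n)), so ground truth carries no sampling
noise; the default concordant fraction 0.685 matches the published value.
Ct tables use Ct = 35 − log2(abundance) + noise, making ΔΔCt exact at zero
noise. All randomness flows from one seed; identical configs are
byte-identical.

What it does not emulate: probe-level replicates, spatial/batch/dye effects,
heavy-tailed or intensity-dependent variance, correlated co-regulation
beyond the planted pairs, isoform structure beyond simple exon chains, and
realistic chromosome-scale gene density. Passing tests therefore demonstrate
correctness of the algorithms under the stated noise model, not robustness
to every artifact of real arrays. Default transcript counts
(1500 coding / 500 lncRNA over 20 × 15 Mb chromosomes) are a desk-scale
stand-in for the ~25 k/36 k-probe array; statistical behavior per transcript
is unaffected by the total count except through the FDR family size.

One interaction worth knowing: quantile normalization presumes comparable
intensity distributions across samples, so simulations in which a large
share of the transcriptome is planted DE will see planted fold changes
compressed by normalization. Study-scale simulations keep planted effects a
small minority, as in real data.

## Pipeline

`run_pipeline` executes inputs → normalize → diffexpr → classify → pairs →
enrich → qpcr → summarize from one YAML config; any stage failure raises a
stage-named error (nonzero exit via the CLI). Summaries use fixed length
bins (<500, 500–1000, 1000–2000, 2000–3000, ≥3000 nt) so the 1–2 kb bin of
the published length distribution is directly comparable. Hierarchical
clustering is average linkage on Euclidean distances of row-z-scored log2
values (a common heatmap default; the study names none), with zero-variance
rows dropped; leaf orders are reported as data, and no figures are rendered.
The volcano table carries signed log2 fold change (negative = down) and
−log10 P. Run logs echo seed, version and parameters but no timestamps, so
fixed-seed outputs are byte-identical.

## Known limitations

* The DE test and the enrichment statistic are documented defaults, not
  reconstructions of the original GeneSpring/enrichment-tool internals; the
  original headline counts (897 lncRNAs / 438 mRNAs) require the raw arrays
  and are out of scope.
* Classification is per transcript (matching transcript-level probes); no
  isoform collapsing to gene level.
* BH families (per RNA class) and the boundary-gap distance convention are
  choices the source material leaves open; both are configurable.
* The qPCR model assumes perfect doubling; no Pfaffl efficiency correction.
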