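# Methods

`shearmap` analyses a two-condition regulatory-genomics experiment —
laminar shear stress (LSS) versus static culture (ST) — from per-region
count matrices, region files, gene annotations, sequences and HiChIP
paired-end tags. This note describes the statistical procedures, their
assumptions and defaults, what the synthetic-data generator does and does
not emulate, and the design choices made where the design was open.

## Coordinates and intervals

All internal coordinates are 0-based half-open (BED convention); 1-based
inclusive input (GTF-lite) is converted at the I/O layer. Merging treats
book-ended intervals as overlapping (bedtools-merge distance 0).
Nearest-gene distances are measured from the region midpoint to the TSS
(the convention of the common peak annotators), signed genomically
(midpoint − TSS), with ties broken by lexicographically smallest gene id
so results are deterministic. Chromosome names are compared as exact
strings; a suspected naming mismatch between inputs raises a warning
rather than being silently normalized.

## Negative-binomial Wald testing

One engine serves DAR, DEG, DBR and differential-loop testing. Counts are
modelled as NB with `Var = μ + α μ²`.

1. **Size factors**: median-of-ratios over features with all-positive
   counts, rescaled to geometric mean 1 (per-sample totals as a fallback
   when no qualifying feature exists). For loop counts, per-sample totals
   of retained pairs are used instead, because loop matrices are small,
   zero-rich and dominated by called (non-null) pairs.
2. **Dispersion**: per-feature method of moments from the pooled
   within-condition variance, shrunk 50/50 toward a least-squares trend
   `α(μ) = a₀/μ + a₁` fitted across features, floored at 1e-8. The trend
   is fitted on the raw (possibly negative) estimates so sampling noise
   averages out instead of biasing the trend upward.
3. **Wald test**: group means on the normalized scale get a 0.5
   pseudocount before the log, `log2FC = log2((μ̂_A+0.5)/(μ̂_B+0.5))`; the
   standard error comes from the delta method on the NB group-mean
   variances; the p-value is the two-sided normal tail of `log2FC/SE`;
   BH adjustment yields padj, with significance at padj < 0.1 by default
   (the conventional adjusted cutoff of DESeq2-style workflows;
   configurable).

This is a deliberately transparent simplification of the DESeq2 family —
no empirical-Bayes dispersion moderation, no LFC shrinkage, no multi-factor
designs. On the 3-vs-3 null harness (2000 features, mean 200, dispersion
0.1) the raw p < 0.05 fraction is ≈ 0.06: mildly anti-conservative, the
expected behaviour of plug-in dispersions at three replicates, and the
reason significance is always taken from the BH-adjusted values. Power at
|log2FC| = 2 and mean 200 exceeds 0.99. Label swap exactly negates every
log2FC and leaves p-values unchanged.

Because median-of-ratios assumes most features are null (or effects are
sign-balanced), a count matrix in which a large one-sided fraction of
features truly changes will partially absorb the effect into the size
factors — the standard limitation of this normalization.

## Motif scanning and enrichment

A motif is a position probability matrix (rows A/C/G/T). Windows score
`Σ log2((p_{b,i}+10⁻³)/0.25)` against a uniform background; both strands
are scanned; a window hits at ≥ 80% of the maximum achievable score;
windows containing N never hit. Enrichment of a motif in foreground
regions (e.g. DARs gaining accessibility) over background regions
(accessible but not differential) uses the exact upper-tail binomial with
`p₀` the background hit fraction clamped to `[1e-12, 1-1e-12]`. Decoy
motifs are column permutations of the query (information content
preserved, consensus destroyed; permutations reproducing the consensus are
rejected). GC-matched background sampling is not implemented — the
simulator's sequences are uniform-composition, so composition matching
would be a no-op there; with real sequences the background set should be
chosen accordingly.

## Peak annotation and integration

Peaks are annotated by centre position with precedence
promoter > TTS > exon > intron > intergenic; the promoter window is
TSS ± 3 kb (a common operational definition of promoter proximity) and the
TTS window ± 1 kb. The accessibility-expression correlation pairs every
significant DAR with its nearest gene, keeps pairs whose gene is a
significant DEG, and reports two-sided Pearson r (multiple DARs nearest to
one gene all contribute pairs — deduplication would discard real
multi-enhancer structure). Co-occupancy calls a region KLF4- (or BRG1-)
positive on ≥ 1 bp overlap with the corresponding differentially bound
set, partitioning regions four ways; when per-region log2FC maps are
provided it also reports the Pearson r between KLF4 binding change and
accessibility change over co-occupied regions. SNPs map to elements by
half-open containment.

## Activity-by-Contact

Candidate elements: resize each peak to 250 bp centred on its summit,
keep the top N by read count (ties broken by coordinate), remove
blacklist overlaps, merge. Activity is the geometric mean of ATAC and
H3K27ac reads-per-million over the candidate set (replicate-summed within
the scored condition); an element with zero signal in either assay has
zero activity. Every gene also gets a promoter element (TSS ± 250 bp)
that is always in the denominator and receives the maximum contact in the
window (self-contact convention).

Contact defaults to the power law `(d + d₀)^(-γ)` with γ = 1 and
d₀ = 5 kb (d₀ avoids the singularity at zero distance; γ = 1 is the
canonical intra-chromosomal decay exponent). When contact records are
supplied — the pipeline feeds each condition's pooled HiChIP map — the
observed count is rescaled onto the power-law axis by the ratio-of-sums
`Σ(d+d₀)^(-γ) / Σ count` over observed pairs (robust to the minority of
genuinely looped pairs) and floored at the power-law value, so unobserved
bins never zero out a prediction. Scores are
`A_e·C_eg / Σ_{e'∈window} A_{e'}·C_{e'g}` over a 5 Mb window: they sum to
1 per gene by construction (or are all zero when every product is zero),
are invariant to rescaling all activities, and increase monotonically in
the element's own activity. The passing threshold is 0.02.

## HiChIP loop calling

Tags are binned at 1 kb by anchor midpoint; intra-chromosomal pairs
closer than 1 kb are discarded (self-ligation regime). The background is
fitted per condition from pooled replicates: distances are log-binned
(50 strata), the mean count per stratum is computed over **all** candidate
bin pairs (observed zeros included) and made monotone non-increasing by
weighted pool-adjacent-violators. Per-anchor coverage bias is the ratio of
a bin's observed coverage to the coverage *expected* under the fitted
decay given that bin's candidate partners — a plain coverage-over-mean
ratio would misread the truncated partner window of bins near a
chromosome end as depletion and systematically over-call loops there. The
expected count of a pair is `decay(d)·bias_i·bias_j`; significance is the
Poisson upper tail with BH over all candidate pairs within 2 Mb
(all-to-all testing), loops at q < 0.01. Anchors are single 1 kb bins;
clustering of adjacent significant pairs is intentionally not performed.

Loops are classified by anchors: P if the bin overlaps any TSS ± 3 kb
window, E if it overlaps an H3K27ac peak and is not P; EP loops carry the
target gene(s) of the promoter anchor. Differential loops reuse the NB
engine on per-replicate loop counts with total-retained-pairs size
factors; gained = significant with log2FC > 0 (LSS over ST). The
KLF4-at-anchor integration reports, per EP loop, the largest-|log2FC|
differentially bound KLF4 region overlapping the enhancer anchor (0 if
none) next to the target gene's expression change, and can flag anchors
absent from a second loop set (e.g. a knockdown condition).

On a null contact map (no planted boost) the caller flags essentially no
pairs at q < 0.05; with the default 8-fold boost it recovers all planted
loops with a false-positive rate ≤ 10⁻⁴ of tested pairs.

## The synthetic study

The generator writes a complete miniature study — candidate regions
(narrowPeak), gene table, ATAC/H3K27ac/KLF4/BRG1/RNA count matrices
(3 + 3 replicates), region sequences, per-condition-per-replicate HiChIP
BEDPE, SNP table — plus truth tables, deterministically from one seed
(byte-identical reruns; all randomness flows through named substreams of
a single `SeedSequence`).

Defaults: one 10 Mb chromosome, 120 genes, 800 candidate regions of
500 bp, 150 planted enhancers, half gaining accessibility under LSS and
half under ST, |log2FC| centred on 2.0 with per-region spread
U[0.6, 1.4]× (so effect-size correlations are estimable), NB dispersion
0.1, baseline mean 200 counts, contact decay γ = 1 with d₀ = 5 kb, loop
boost 8. These are the study conditions every property is evaluated
under.

Design choices worth knowing:

- **Placement.** Each planted enhancer sits 10–80 kb from its target
  TSS, constrained so the target remains the nearest gene — the
  nearest-gene pairing then coincides with the planted link, which is the
  regime in which a nearest-gene correlation analysis is meaningful.
  Background regions are uniform over the genome.
- **Signal coupling.** A planted enhancer carries its boosted ATAC and
  H3K27ac signal in its *active* condition (LSS for opening enhancers, ST
  for closing ones), so gains and losses are symmetric in magnitude;
  KLF4 signal rises only at opening, motif-bearing enhancers, while BRG1
  follows accessibility in both directions — mirroring a
  factor-recruits-remodeler architecture. Promoter features are strong in
  both assays (mean 2000), as real TSSs are, which keeps the ABC
  denominator realistic. H3K27ac at inactive background regions is low
  (mean 30).
- **Sequences.** Region sequences are uniform A/C/G/T with a GC-rich
  10-mer KLF-like consensus inserted at the summit of every opening
  enhancer and of a 5% decoy fraction of background regions (KLF4 binds
  the decoys but not differentially).
- **Expression.** Gene means are log-normal around 200; a linked gene's
  LSS mean is multiplied by `2^(Σ w·lfc)` over its enhancers
  (w ∈ U[0.8, 1.2]), so enhancer activity drives expression.
- **Contacts.** Tags are generated only between peak-summit and TSS bins
  (HiChIP coverage is peak-centric), Poisson with rate
  `N·(d+d₀)^(-γ)` and an 8-fold boost on a planted loop's pair in its
  enhancer's active condition (opening enhancers gain their loop with
  LSS; closing enhancers keep theirs under ST — loops "lost" with flow).
  At the default rate a condition pools ≈ 200k tags.
- **SNPs.** 22 SNPs are placed within ±100 bp of the summit of linked
  enhancers (where a motif-disrupting regulatory variant would sit, and
  inside the 250 bp ABC element); 30 decoys land outside all candidate
  regions.

What the simulator does **not** emulate — and hence what passing tests do
not certify about real data: GC-composition and mappability biases,
chromatin-domain structure (TADs, A/B compartments), multi-chromosome
genomes, overdispersed or duplicate-laden HiChIP tags, enhancers
regulating multiple genes, gene-body reads, batch effects, and replicate
library-size imbalance beyond what size factors absorb.

## Pipeline and reproducibility

Stages (`simulate`, `dar`, `deg`, `dbr`, `motifs`, `annotate`, `abc`,
`loops`, `integrate`, `all`) each re-read their inputs and write TSV/JSON
outputs plus a run manifest (config, package version, input checksums);
`all` also writes a markdown report with every summary table. The report
is plain markdown by design — every figure-like artefact is a table that
diffs cleanly and needs no plotting backend. The CLI accepts `--threads`
for interface compatibility but all computation is vectorized
single-process and results never depend on it. The end-to-end run on the
default study takes a few seconds on one CPU; problem sizes throughout
(2000-feature null harnesses, ~150k tested bin pairs, 1000-case oracle
sweeps) were chosen so the whole test suite runs in well under a minute
while keeping Monte-Carlo bands tight.

## Known limitations

- The NB test is mildly anti-conservative at 3 replicates (raw
  p < 0.05 fraction ≈ 0.06 on the null); interpretation should rest on
  the BH-adjusted values.
- The binomial motif test clamps a zero background rate to 1e-12, which
  makes a single foreground hit against an all-negative background look
  extreme; with small region sets the fold and fractions should be read
  alongside the p-value.
- ABC precision is evaluated against single-target planted links, so an
  element legitimately predicted for a second nearby gene counts against
  precision; on default data precision is ≈ 0.7 with recall 1.0.
- The loop caller tests single-bin pairs; broad anchors spanning several
  bins would be fragmented rather than clustered.
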