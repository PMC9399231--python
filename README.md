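# shearmap

Endothelial cells remodel their enhancer landscape when exposed to
physiologic laminar shear stress (LSS): chromatin opens at KLF-motif
sites, KLF4 and the SWI/SNF ATPase BRG1 co-occupy those regions, active
enhancers loop to the promoters of flow-responsive genes, and non-coding
variants falling inside such enhancers can be tied to the genes they
regulate. `shearmap` implements the computational layers of this kind of
two-condition (LSS vs static, ST) epigenomics study as a reusable,
tested Python library:

- **Differential testing** — one negative-binomial Wald engine
  (median-of-ratios size factors, method-of-moments dispersion shrunk
  toward a fitted mean-dispersion trend, delta-method standard errors,
  Benjamini–Hochberg adjustment) behind differentially accessible regions
  (ATAC), differentially expressed genes (RNA), differentially bound
  regions (TF/histone ChIP), and differential loops (HiChIP).
- **Motif enrichment** — PWM log-odds scanning on both strands and an
  exact upper-tail binomial test of foreground vs background region sets.
- **Peak annotation & integration** — promoter/TTS/exon/intron/intergenic
  annotation by peak centre, nearest-TSS distances, the DAR-vs-DEG
  Pearson correlation, KLF4/BRG1 co-occupancy partitions, and
  SNP-to-enhancer-to-gene tables.
- **Activity-by-Contact (ABC)** — candidate elements resized to 250 bp
  around peak summits, ranked, blacklist-filtered and merged; activity
  `A = sqrt(ATAC_rpm × H3K27ac_rpm)`; contact `C` from user-supplied
  contact records (e.g. a HiChIP map) floored at a `(d + d0)^(-γ)` power
  law; the score of element *e* for gene *g* is
  `A_e·C_eg / Σ_{e'} A_{e'}·C_{e'g}` over the gene's 5 Mb window, with
  passing threshold 0.02.
- **HiChIP loop calling** — 1 kb binning (minimum interaction size 1 kb),
  a monotone distance-decay background (pool-adjacent-violators) with
  per-anchor coverage bias, Poisson upper-tail p-values BH-adjusted over
  all candidate bin pairs, E/P anchor classification, and differential
  loops via the shared NB engine.
- **Synthetic data with planted truth** — a 10 Mb toy genome generator
  that plants DARs, motifs, enhancer→gene links, loops and DEG effects,
  so every stage can be scored against a known answer.

## Worked example

```bash
python examples/01_differential_accessibility.py
```

prints (seed 1):

```
differentially accessible regions at BH-adjusted p < 0.1: 81 open with LSS, 85 close
planted DARs: 150; recovered: 144 (sensitivity 0.96)
```

i.e. of 920 regions counted across 3 + 3 replicates, 166 are called
differential and 144 of the 150 planted effects are recovered. The other
examples exercise one capability each:

```bash
python examples/02_abc_predictions.py      # enhancer-gene links: recall 1.00, precision 0.72
python examples/03_hichip_loops.py         # 150/150 planted EP loops at q < 0.01
python examples/04_motifs_and_integration.py  # full report, r = 0.84, 22 SNPs -> 26 genes
```

The same stages are available as a thin CLI:

```bash
shearmap --data-dir data --outdir results --seed 1 simulate
shearmap --data-dir data --outdir results all     # writes results/report.md
```

`results/report.md` contains the DAR/DEG tallies, annotation pie counts,
nearest-TSS distance histogram, motif table, DAR–DEG correlation,
co-occupancy fractions, ABC summary, loop summary, KLF4-at-anchor
integration and the SNP table.

## Library layout

| module | contents |
|---|---|
| `shearmap.intervals` | `GenomicInterval`/`Peak`/`Gene`, overlap, merge, summit-centred resize, nearest TSS |
| `shearmap.io` | BED/narrowPeak/BEDPE/GTF-lite/TSV/PWM/FASTA readers and writers, `CountMatrix` |
| `shearmap.differential` | size factors, NB Wald test, BH, exact binomial/Poisson/hypergeometric tails |
| `shearmap.motifs` | `PWM`, scanning, binomial enrichment, shuffled-column decoys |
| `shearmap.annotate` | peak annotation, distance histograms, DAR–DEG correlation, co-occupancy, SNP overlap |
| `shearmap.abc_model` | candidate elements, activity, contact models, ABC scores |
| `shearmap.loops` | binning, decay background, loop calling/classification/differential, KLF4-at-anchor integration |
| `shearmap.synthetic` | study simulator and truth tables |
| `shearmap.pipeline`, `shearmap.cli` | stage orchestration, markdown report, click CLI |

See `docs/methods.md` for the statistical models, parameter defaults and
the simulator's design assumptions.
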