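"""Peak annotation, nearest-gene statistics, and occupancy integration.

Covers the descriptive layers of the analysis: genomic-category
annotation of peaks (promoter / TTS / exon / intron / intergenic by peak
centre with fixed precedence), distance-to-nearest-TSS histograms, the
accessibility-vs-expression correlation of differential regions paired
with their nearest differential gene, four-way KLF4/BRG1 co-occupancy
partitions of differential regions, and SNP-to-element-to-target-gene
mapping over ABC predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Gene, GenomicInterval, Peak, nearest_tss
from .io import SNPRecord

CATEGORIES = ["promoter", "TTS", "exon", "intron", "intergenic"]


class _IntervalIndex:
    """Sorted-start index answering 'does this point/interval overlap any?'"""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            self._by_chrom[chrom] = (
                np.array([s for s, _ in spans]),
                np.array([e for _, e in spans]),
            )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        hi = np.searchsorted(starts, end, side="left")
        return bool((ends[:hi] > start).any())


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    exons: Optional[Sequence[GenomicInterval]] = None,
    promoter_bp: int = 3000,
    tts_bp: int = 1000,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Annotate each peak by its centre position with fixed precedence
    promoter > TTS > exon > intron > intergenic.

    Promoter = TSS +/- promoter_bp; TTS = transcription end +/- tts_bp;
    intron = inside a gene body but in none of the higher categories.
    Returns the per-peak table and a category tally (the pie-chart data).
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    prom_idx = _IntervalIndex(
        [
            GenomicInterval(g.interval.chrom, max(0, g.tss - promoter_bp), g.tss + promoter_bp + 1)
            for g in genes
        ]
    )
    tts_idx = _IntervalIndex(
        [
            GenomicInterval(g.interval.chrom, max(0, g.tes - tts_bp), g.tes + tts_bp + 1)
            for g in genes
        ]
    )
    exon_idx = _IntervalIndex(list(exons)) if exons else None
    body_idx = _IntervalIndex([g.interval for g in genes])

    rows = []
    for p in peaks:
        center = p.interval.midpoint
        chrom = p.interval.chrom
        if prom_idx.overlaps(chrom, center, center + 1):
            cat = "promoter"
        elif tts_idx.overlaps(chrom, center, center + 1):
            cat = "TTS"
        elif exon_idx is not None and exon_idx.overlaps(chrom, center, center + 1):
            cat = "exon"
        elif body_idx.overlaps(chrom, center, center + 1):
            cat = "intron"
        else:
            cat = "intergenic"
        gene, dist = nearest_tss(p.interval, genes)
        rows.append(
            {
                "peak_id": p.name,
                "category": cat,
                "nearest_gene_id": gene.gene_id if gene else "",
                "signed_distance_bp": dist if dist is not None else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    tally = {c: int((table["category"] == c).sum()) for c in CATEGORIES}
    return table, tally


def distance_distribution(
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    bin_edges: Sequence[float] = (0, 1e3, 1e4, 1e5, 1e6, np.inf),
) -> pd.DataFrame:
    """Histogram of |distance to nearest TSS| over half-open bins [lo, hi)."""
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    dists = []
    for p in peaks:
        _, d = nearest_tss(p.interval, genes)
        if d is not None:
            dists.append(abs(d))
    counts = np.zeros(len(edges) - 1, dtype=int)
    for d in dists:
        j = np.searchsorted(edges, d, side="right") - 1
        if 0 <= j < len(counts):
            counts[j] += 1
    return pd.DataFrame(
        {"lo": edges[:-1], "hi": edges[1:], "count": counts}
    )


def dar_deg_correlation(
    dar_results: pd.DataFrame,
    peaks: Sequence[Peak],
    deg_results: pd.DataFrame,
    genes: Sequence[Gene],
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of DAR log2FC with the log2FC of each DAR's
    nearest gene, restricted to nearest genes that are significant DEG.

    A gene nearest to several DARs contributes every (DAR, gene) pair.
    Returns (r, two-sided p, paired table); (nan, nan, table) with fewer
    than 3 pairs.
    """
    peak_by_id = {p.name: p for p in peaks}
    deg = deg_results.set_index("feature_id")
    rows = []
    for rec in dar_results.itertuples(index=False):
        if not rec.significant:
            continue
        p = peak_by_id.get(rec.feature_id)
        if p is None:
            continue
        gene, dist = nearest_tss(p.interval, genes)
        if gene is None or gene.gene_id not in deg.index:
            continue
        grow = deg.loc[gene.gene_id]
        if not bool(grow["significant"]):
            continue
        rows.append(
            {
                "region_id": rec.feature_id,
                "gene_id": gene.gene_id,
                "distance_bp": dist,
                "dar_log2fc": rec.log2fc,
                "deg_log2fc": grow["log2fc"],
            }
        )
    table = pd.DataFrame(
        rows, columns=["region_id", "gene_id", "distance_bp", "dar_log2fc", "deg_log2fc"]
    )
    if len(table) < 3:
        return float("nan"), float("nan"), table
    r, p = stats.pearsonr(table["dar_log2fc"], table["deg_log2fc"])
    return float(r), float(p), table


@dataclass
class CooccupancySummary:
    n_dar: int
    n_both: int
    n_klf4_only: int
    n_brg1_only: int
    n_neither: int
    klf4_accessibility_r: Optional[float] = None

    def __post_init__(self) -> None:
        parts = self.n_both + self.n_klf4_only + self.n_brg1_only + self.n_neither
        if parts != self.n_dar:
            raise ValueError("co-occupancy counts must partition n_dar")

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_dar
        return {
            "both": self.n_both / n,
            "klf4_only": self.n_klf4_only / n,
            "brg1_only": self.n_brg1_only / n,
            "neither": self.n_neither / n,
        }


def cooccupancy(
    dar_regions: Sequence[Peak],
    klf4_dbr: Sequence[GenomicInterval],
    brg1_dbr: Sequence[GenomicInterval],
    klf4_log2fc: Optional[Mapping[str, float]] = None,
    atac_log2fc: Optional[Mapping[str, float]] = None,
) -> tuple[CooccupancySummary, pd.DataFrame]:
    """Partition differential regions by >=1 bp overlap with differentially
    bound KLF4 and BRG1 region sets.

    When per-region KLF4 and accessibility log2FC maps are supplied, also
    reports the Pearson r between the two over co-occupied regions.
    """
    if not dar_regions:
        raise ValueError("empty DAR set")
    klf4_idx = _IntervalIndex(list(klf4_dbr))
    brg1_idx = _IntervalIndex(list(brg1_dbr))
    rows = []
    for p in dar_regions:
        iv = p.interval
        k = klf4_idx.overlaps(iv.chrom, iv.start, iv.end)
        b = brg1_idx.overlaps(iv.chrom, iv.start, iv.end)
        rows.append({"region_id": p.name, "klf4": k, "brg1": b})
    flags = pd.DataFrame(rows)
    n_both = int((flags["klf4"] & flags["brg1"]).sum())
    n_k = int((flags["klf4"] & ~flags["brg1"]).sum())
    n_b = int((~flags["klf4"] & flags["brg1"]).sum())
    n_n = int((~flags["klf4"] & ~flags["brg1"]).sum())
    r: Optional[float] = None
    if klf4_log2fc is not None and atac_log2fc is not None:
        co = flags[flags["klf4"] & flags["brg1"]]["region_id"]
        xs = [klf4_log2fc[i] for i in co if i in klf4_log2fc and i in atac_log2fc]
        ys = [atac_log2fc[i] for i in co if i in klf4_log2fc and i in atac_log2fc]
        if len(xs) >= 3:
            r = float(stats.pearsonr(xs, ys)[0])
    summary = CooccupancySummary(len(flags), n_both, n_k, n_b, n_n, r)
    return summary, flags


def snp_overlap(
    snps: Sequence[SNPRecord], predictions: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Map SNPs to the ABC-predicted elements containing them.

    ``predictions`` needs columns element_id, chrom, start, end, gene_id,
    score (passing predictions; a ``passes`` column, when present, filters
    the table). Containment is half-open: a SNP at the element start is
    inside, one at the end coordinate is not. Returns the (rsid, element,
    gene, score) table and a summary with distinct SNP and gene counts.
    """
    preds = predictions
    if "passes" in preds.columns:
        preds = preds[preds["passes"]]
    rows = []
    for s in snps:
        hit = preds[
            (preds["chrom"] == s.chrom)
            & (preds["start"] <= s.pos)
            & (s.pos < preds["end"])
        ]
        for rec in hit.itertuples(index=False):
            rows.append(
                {
                    "rsid": s.rsid,
                    "element_id": rec.element_id,
                    "gene_id": rec.gene_id,
                    "abc_score": rec.score,
                }
            )
    table = pd.DataFrame(rows, columns=["rsid", "element_id", "gene_id", "abc_score"])
    summary = {
        "n_snps_in_elements": int(table["rsid"].nunique()),
        "n_target_genes": int(table["gene_id"].nunique()),
    }
    return table, summary
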