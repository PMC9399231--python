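"""Peak annotation and integration layers against rule-by-rule oracles."""

import numpy as np
import pandas as pd
import pytest

from shearmap.annotate import (
    CATEGORIES,
    CooccupancySummary,
    annotate_peaks,
    cooccupancy,
    dar_deg_correlation,
    distance_distribution,
    snp_overlap,
)
from shearmap.intervals import Gene, GenomicInterval, Peak
from shearmap.io import SNPRecord


def peak(start, end, name="p", chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), (end - start) // 2, 0.0, name)


def gene(gid, start, end, strand="+", chrom="chr1"):
    return Gene(gid, gid, GenomicInterval(chrom, start, end), strand)


def reference_category(center, genes, exons, promoter_bp, tts_bp):
    """Independent rule-table evaluation of the category precedence."""
    for g in genes:
        if abs(center - g.tss) <= promoter_bp:
            return "promoter"
    for g in genes:
        if abs(center - g.tes) <= tts_bp:
            return "TTS"
    for e in exons or []:
        if e.start <= center < e.end:
            return "exon"
    for g in genes:
        if g.interval.start <= center < g.interval.end:
            return "intron"
    return "intergenic"


class TestAnnotatePeaks:
    def test_peak_on_tss_is_promoter(self):
        genes = [gene("g1", 10_000, 15_000)]
        table, tally = annotate_peaks([peak(9_900, 10_100)], genes)
        assert table.iloc[0]["category"] == "promoter"
        assert tally["promoter"] == 1

    def test_far_peak_is_intergenic(self):
        genes = [gene("g1", 10_000, 15_000)]
        table, _ = annotate_peaks([peak(60_000, 60_500)], genes)
        assert table.iloc[0]["category"] == "intergenic"

    def test_every_peak_gets_exactly_one_category(self):
        rng = np.random.default_rng(20)
        genes = [
            gene(f"g{i}", s := int(rng.integers(0, 900_000)), s + int(rng.integers(2_000, 20_000)),
                 "+" if rng.random() < 0.5 else "-")
            for i in range(30)
        ]
        peaks = [peak(int(s), int(s) + 500, f"p{i}") for i, s in
                 enumerate(rng.integers(0, 950_000, size=500))]
        table, tally = annotate_peaks(peaks, genes)
        assert set(table["category"]) <= set(CATEGORIES)
        assert sum(tally.values()) == len(peaks)

    def test_matches_rule_table_oracle(self):
        rng = np.random.default_rng(21)
        genes = [
            gene(f"g{i}", s := int(rng.integers(0, 500_000)), s + int(rng.integers(2_000, 20_000)),
                 "+" if rng.random() < 0.5 else "-")
            for i in range(20)
        ]
        exons = [
            GenomicInterval("chr1", g.interval.start, g.interval.start + 500) for g in genes
        ]
        peaks = []
        for i in range(500):
            s = int(rng.integers(0, 520_000))
            peaks.append(peak(s, s + int(rng.integers(100, 1_000)), f"p{i}"))
        table, _ = annotate_peaks(peaks, genes, exons=exons)
        for p, rec in zip(peaks, table.itertuples(index=False)):
            assert rec.category == reference_category(
                p.interval.midpoint, genes, exons, 3000, 1000
            ), p.name


class TestDistanceDistribution:
    def test_all_zero_distance_in_first_bin(self):
        genes = [gene("g1", 10_000, 15_000)]
        hist = distance_distribution([peak(9_750, 10_250)], genes)
        assert hist["count"].tolist() == [1, 0, 0, 0, 0]

    def test_empty_peaks_all_zero(self):
        genes = [gene("g1", 10_000, 15_000)]
        assert distance_distribution([], genes)["count"].sum() == 0

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            distance_distribution([], [gene("g1", 0, 10)], bin_edges=[0, 10, 5])

    def test_matches_direct_binning(self):
        rng = np.random.default_rng(22)
        genes = [gene(f"g{i}", int(t), int(t) + 1000) for i, t in
                 enumerate(rng.integers(0, 1_000_000, size=40))]
        peaks = [peak(s, s + 200, f"p{i}") for i, s in
                 enumerate(rng.integers(0, 1_000_000, size=300))]
        edges = [0, 1e3, 1e4, 1e5, 1e6, np.inf]
        hist = distance_distribution(peaks, genes, edges)
        tss = np.array([g.tss for g in genes])
        dists = [abs(int(np.min(np.abs(p.interval.midpoint - tss)))) for p in peaks]
        ref, _ = np.histogram(dists, bins=edges)
        assert hist["count"].tolist() == ref.tolist()


class TestDarDegCorrelation:
    def results(self, ids, lfc, sig):
        return pd.DataFrame(
            {"feature_id": ids, "base_mean": 1.0, "log2fc": lfc, "se": 1.0,
             "pvalue": 0.01, "padj": 0.01, "significant": sig}
        )

    def setup_pairs(self, slopes):
        genes = [gene(f"g{i}", 100_000 * (i + 1), 100_000 * (i + 1) + 5_000)
                 for i in range(len(slopes))]
        peaks = [peak(100_000 * (i + 1) + 20_000, 100_000 * (i + 1) + 20_500, f"p{i}")
                 for i in range(len(slopes))]
        dar = self.results([p.name for p in peaks], [float(s) for s in slopes], True)
        deg = self.results([g.gene_id for g in genes],
                           [float(s) for s in slopes], True)
        return dar, peaks, deg, genes

    def test_perfect_positive_line(self):
        dar, peaks, deg, genes = self.setup_pairs([1, 2, 3, 4])
        r, p, table = dar_deg_correlation(dar, peaks, deg, genes)
        assert r == pytest.approx(1.0)
        assert len(table) == 4

    def test_antisymmetric_line(self):
        dar, peaks, deg, genes = self.setup_pairs([1, 2, 3])
        deg["log2fc"] = -deg["log2fc"]
        r, _, _ = dar_deg_correlation(dar, peaks, deg, genes)
        assert r == pytest.approx(-1.0)

    def test_insufficient_pairs(self):
        dar, peaks, deg, genes = self.setup_pairs([1, 2])
        r, p, table = dar_deg_correlation(dar, peaks, deg, genes)
        assert np.isnan(r) and np.isnan(p) and len(table) == 2

    def test_order_invariance(self):
        dar, peaks, deg, genes = self.setup_pairs([3, 1, 4, 1, 5])
        r1, p1, _ = dar_deg_correlation(dar, peaks, deg, genes)
        r2, p2, _ = dar_deg_correlation(
            dar.iloc[::-1].reset_index(drop=True), peaks[::-1],
            deg.iloc[::-1].reset_index(drop=True), genes[::-1],
        )
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)


class TestCooccupancy:
    def test_identical_sets_all_both(self):
        peaks = [peak(i * 10_000, i * 10_000 + 500, f"p{i}") for i in range(10)]
        ivs = [p.interval for p in peaks]
        summary, _ = cooccupancy(peaks, ivs, ivs)
        assert summary.fractions["both"] == 1.0

    def test_disjoint_sets_all_neither(self):
        peaks = [peak(i * 10_000, i * 10_000 + 500, f"p{i}") for i in range(10)]
        other = [GenomicInterval("chr1", 900_000 + i * 1000, 900_000 + i * 1000 + 100)
                 for i in range(5)]
        summary, _ = cooccupancy(peaks, other, other)
        assert summary.fractions["neither"] == 1.0

    def test_empty_dar_rejected(self):
        with pytest.raises(ValueError):
            cooccupancy([], [], [])

    def test_partition_matches_brute_force(self):
        rng = np.random.default_rng(23)
        peaks = [peak(s, s + int(rng.integers(100, 800)), f"p{i}")
                 for i, s in enumerate(rng.integers(0, 200_000, size=300))]
        klf4 = [GenomicInterval("chr1", s, s + int(rng.integers(100, 800)))
                for s in rng.integers(0, 200_000, size=80)]
        brg1 = [GenomicInterval("chr1", s, s + int(rng.integers(100, 800)))
                for s in rng.integers(0, 200_000, size=80)]
        summary, flags = cooccupancy(peaks, klf4, brg1)

        def any_overlap(iv, ivs):
            return any(iv.start < o.end and o.start < iv.end for o in ivs)

        for p, rec in zip(peaks, flags.itertuples(index=False)):
            assert rec.klf4 == any_overlap(p.interval, klf4)
            assert rec.brg1 == any_overlap(p.interval, brg1)
        assert (
            summary.n_both + summary.n_klf4_only + summary.n_brg1_only + summary.n_neither
            == summary.n_dar == 300
        )

    def test_partition_invariant_enforced(self):
        with pytest.raises(ValueError):
            CooccupancySummary(n_dar=5, n_both=1, n_klf4_only=1, n_brg1_only=1, n_neither=1)


class TestSnpOverlap:
    def predictions(self):
        return pd.DataFrame(
            {
                "element_id": ["e1", "e2"],
                "chrom": ["chr1", "chr1"],
                "start": [1000, 5000],
                "end": [1250, 5250],
                "gene_id": ["g1", "g2"],
                "score": [0.5, 0.3],
                "passes": [True, True],
                "is_promoter": [False, False],
            }
        )

    def test_half_open_boundaries(self):
        preds = self.predictions()
        table, summary = snp_overlap(
            [SNPRecord("rs_start", "chr1", 1000), SNPRecord("rs_end", "chr1", 1250)],
            preds,
        )
        assert table["rsid"].tolist() == ["rs_start"]
        assert summary["n_snps_in_elements"] == 1

    def test_empty_intersection_allowed(self):
        table, summary = snp_overlap([SNPRecord("rs1", "chr1", 99)], self.predictions())
        assert len(table) == 0 and summary["n_target_genes"] == 0

    def test_planted_snps_recovered_on_synthetic_data(self, default_run):
        pipe, summary, truth = default_run
        sn = summary["integration"]["snp"]
        # every planted SNP sits in a passing element; decoys sit in none
        assert sn["n_snps_in_elements"] == 22
        table = pd.read_csv(pipe.outdir / "snp_targets.tsv", sep="\t")
        assert all(r.startswith("rs9") for r in table["rsid"])  # no decoys (rs8...)
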