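"""Loop calling: binning conservation, decay fit, Poisson tails,
classification rules and differential/integration logic."""

import math

import numpy as np
import pandas as pd
import pytest

from shearmap.intervals import Gene, GenomicInterval
from shearmap.loops import (
    BinnedContacts,
    bin_contacts,
    call_loops,
    classify_loops,
    differential_loops,
    fit_decay,
    klf4_at_anchors,
    loop_count_matrix,
)


def pets_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "count"],
    )


def pet(p1, p2, count=1, chrom="chr1"):
    return (chrom, p1, p1 + 1, chrom, p2, p2 + 1, ".", count)


class TestBinContacts:
    def test_floor_arithmetic(self):
        b = bin_contacts(pets_frame([pet(1500, 3500)]), resolution=1000)
        rec = b.pairs.iloc[0]
        assert (rec["bin1"], rec["bin2"]) == (1, 3)

    def test_minimum_size_filter_drops_short_pairs(self):
        b = bin_contacts(pets_frame([pet(1200, 1700)]), resolution=1000, min_distance=1000)
        assert len(b.pairs) == 0

    def test_inter_chromosomal_dropped(self):
        df = pets_frame([("chr1", 0, 1, "chr2", 5000, 5001, ".", 1)])
        assert len(bin_contacts(df).pairs) == 0

    def test_count_conservation(self):
        rng = np.random.default_rng(40)
        rows = []
        total_kept = 0
        for _ in range(10_000):
            p1 = int(rng.integers(0, 1_000_000))
            p2 = p1 + int(rng.integers(0, 50_000))
            c = int(rng.integers(1, 4))
            rows.append(pet(p1, p2, c))
            if abs(p2 // 1000 - p1 // 1000) >= 1:
                total_kept += c
        b = bin_contacts(pets_frame(rows))
        assert b.total_pairs == total_kept == b.pairs["count"].sum()
        assert b.coverage["coverage"].sum() == 2 * total_kept


class TestFitDecay:
    def powerlaw_map(self, seed=41, n_bins=200, rate=500.0):
        rng = np.random.default_rng(seed)
        bins = np.arange(n_bins)
        rows = []
        for i in range(n_bins):
            for j in range(i + 1, n_bins):
                d = (j - i) * 1000
                c = rng.poisson(rate / (d + 5000) * 1000)
                if c > 0:
                    rows.append(pet(i * 1000 + 500, j * 1000 + 500, int(c)))
        return bin_contacts(pets_frame(rows))

    def test_decreasing_on_power_law_map(self):
        b = self.powerlaw_map()
        model = fit_decay(b, n_dist_bins=20)
        assert np.all(np.diff(model.means) <= 1e-12)
        assert model.means[0] > model.means[-1]

    def test_constant_on_uniform_map(self):
        rows = [pet(i * 1000 + 500, j * 1000 + 500, 5)
                for i in range(50) for j in range(i + 1, 50)]
        model = fit_decay(bin_contacts(pets_frame(rows)), n_dist_bins=10)
        assert np.allclose(model.means, 5.0)

    def test_single_distance_global_mean(self):
        # one candidate pair per chromosome, all at the same separation
        rows = [pet(500, 5_500, c, chrom=f"chr{i}") for i, c in enumerate([2, 4, 6])]
        model = fit_decay(bin_contacts(pets_frame(rows)))
        assert np.allclose(model.means[model.means > 0], 4.0)

    def test_empty_input_rejected(self):
        empty = bin_contacts(pets_frame([]))
        with pytest.raises(ValueError):
            fit_decay(empty)


class TestCallLoops:
    def test_zero_count_p_is_one(self):
        b = self.simple_map()
        model = fit_decay(b)
        _, tested = call_loops(b, model)
        zeros = tested[tested["count"] == 0]
        assert (zeros["p"] == 1.0).all()

    def simple_map(self):
        rows = [pet(i * 1000 + 500, j * 1000 + 500, 3)
                for i in range(30) for j in range(i + 1, 30)]
        rows.append(pet(2_500, 22_500, 40))  # one strong pair
        return bin_contacts(pets_frame(rows))

    def test_poisson_tail_matches_exact_sum(self):
        b = self.simple_map()
        model = fit_decay(b)
        _, tested = call_loops(b, model)
        rec = tested[tested["count"] > 0].iloc[0]
        lam, k = rec["expected"], int(rec["count"])
        exact = 1.0 - sum(math.exp(-lam) * lam**j / math.factorial(j) for j in range(k))
        assert rec["p"] == pytest.approx(exact, abs=1e-12)

    def test_strong_pair_called(self):
        b = self.simple_map()
        called, _ = call_loops(b, fit_decay(b), q_threshold=0.01)
        assert ((called["bin1"] == 2) & (called["bin2"] == 22)).any()

    def test_q_threshold_validation(self):
        b = self.simple_map()
        with pytest.raises(ValueError):
            call_loops(b, fit_decay(b), q_threshold=0.0)


class TestClassifyLoops:
    def setup(self):
        genes = [Gene("g1", "g1", GenomicInterval("chr1", 100_000, 110_000), "+")]
        k27 = [GenomicInterval("chr1", 50_200, 50_700)]
        loops = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "bin1": [50, 100, 30],
                "bin2": [100, 200, 40],
                "count": [10, 10, 10],
                "loop_id": ["a", "b", "c"],
            }
        )
        # second promoter for the PP case
        genes.append(Gene("g2", "g2", GenomicInterval("chr1", 200_000, 210_000), "+"))
        return loops, k27, genes

    def test_rule_table(self):
        loops, k27, genes = self.setup()
        out = classify_loops(loops, k27, genes)
        by_id = out.set_index("loop_id")
        assert by_id.loc["a", "loop_class"] == "EP"
        assert by_id.loc["a", "target_gene"] == "g1"
        assert by_id.loc["a", "enhancer_bin"] == 50
        assert by_id.loc["b", "loop_class"] == "PP"
        assert by_id.loc["c", "loop_class"] == "other"

    def test_order_invariance(self):
        loops, k27, genes = self.setup()
        a = classify_loops(loops, k27, genes)
        b = classify_loops(loops.iloc[::-1].reset_index(drop=True), k27, genes)
        merged = a.merge(b, on="loop_id", suffixes=("_a", "_b"))
        assert (merged["loop_class_a"] == merged["loop_class_b"]).all()


def binned_from_counts(pair_counts, resolution=1000):
    rows = [pet(b1 * 1000 + 500, b2 * 1000 + 500, c) for (b1, b2), c in pair_counts.items()]
    return bin_contacts(pets_frame(rows), resolution)


class TestDifferentialLoops:
    def test_identical_counts_stable(self):
        pairs = {(i, i + 10): 20 for i in range(30)}
        binned = {f"{c}_rep{r}": binned_from_counts(pairs)
                  for c in ("LSS", "ST") for r in (1, 2, 3)}
        cond = {s: s.split("_")[0] for s in binned}
        loops = pd.DataFrame(
            {
                "chrom": "chr1",
                "bin1": [i for i in range(30)],
                "bin2": [i + 10 for i in range(30)],
                "count": 20,
                "loop_id": [f"chr1:{i}-{i+10}" for i in range(30)],
                "loop_class": "EP",
            }
        )
        out = differential_loops(loops, binned, cond)
        assert (out["differential"] == "stable").all()

    def test_boosted_loops_flagged_gained(self):
        # 10 LSS-boosted loops among 290 background pairs so the boost
        # barely moves per-sample totals (as in the generator)
        rng = np.random.default_rng(43)
        n_pl, n_all = 10, 300
        binned = {}
        for c in ("LSS", "ST"):
            for r in (1, 2, 3):
                pairs = {}
                for i in range(n_all):
                    lam = 40 if (c == "LSS" and i < n_pl) else 5
                    pairs[(i, i + 15)] = int(rng.poisson(lam)) + 1
                binned[f"{c}_rep{r}"] = binned_from_counts(pairs)
        cond = {s: s.split("_")[0] for s in binned}
        loops = pd.DataFrame(
            {
                "chrom": "chr1",
                "bin1": list(range(n_all)),
                "bin2": [i + 15 for i in range(n_all)],
                "count": 1,
                "loop_id": [f"chr1:{i}-{i+15}" for i in range(n_all)],
                "loop_class": "EP",
            }
        )
        out = differential_loops(loops, binned, cond)
        assert (out["differential"][:n_pl] == "gained").mean() >= 0.8
        assert (out["differential"][n_pl:] == "stable").mean() >= 0.8

    def test_absent_loop_counts_zero_not_error(self):
        binned = {f"{c}_rep{r}": binned_from_counts({(0, 10): 5})
                  for c in ("LSS", "ST") for r in (1, 2, 3)}
        cond = {s: s.split("_")[0] for s in binned}
        loops = pd.DataFrame(
            {"chrom": ["chr1"], "bin1": [3], "bin2": [30], "count": [0],
             "loop_id": ["chr1:3-30"], "loop_class": ["EP"]}
        )
        m, sf = loop_count_matrix(loops, binned, cond)
        assert (m.counts == 0).all()


class TestKlf4AtAnchors:
    def ep_loops(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "bin1": [50, 70],
                "bin2": [100, 100],
                "loop_id": ["l1", "l2"],
                "loop_class": ["EP", "EP"],
                "target_gene": ["g1", "g1"],
                "enhancer_bin": [50, 70],
            }
        )

    def deg(self):
        return pd.DataFrame(
            {"feature_id": ["g1"], "base_mean": [10.0], "log2fc": [1.5], "se": [0.1],
             "pvalue": [1e-5], "padj": [1e-4], "significant": [True]}
        )

    def test_no_overlap_summary_zeros(self):
        dbr = pd.DataFrame(columns=["region_id", "chrom", "start", "end", "log2fc"])
        table, summary = klf4_at_anchors(self.ep_loops(), dbr, self.deg())
        assert summary["n_anchors_with_differential_klf4"] == 0
        assert (table["klf4_log2fc"] == 0).all()

    def test_largest_abs_log2fc_reported_on_tie(self):
        dbr = pd.DataFrame(
            {
                "region_id": ["r1", "r2"],
                "chrom": ["chr1", "chr1"],
                "start": [50_100, 50_600],
                "end": [50_400, 50_900],
                "log2fc": [1.0, -2.5],
            }
        )
        table, summary = klf4_at_anchors(self.ep_loops(), dbr, self.deg())
        l1 = table[table["loop_id"] == "l1"].iloc[0]
        assert l1["klf4_log2fc"] == -2.5
        assert summary["n_target_deg"] == 1

    def test_second_loop_set_flags_lost_anchors(self):
        second = self.ep_loops().iloc[:1]
        table, summary = klf4_at_anchors(
            self.ep_loops(),
            pd.DataFrame({"region_id": ["r1"], "chrom": ["chr1"], "start": [70_100],
                          "end": [70_300], "log2fc": [2.0]}),
            self.deg(),
            second_ep_loops=second,
        )
        lost = table.set_index("loop_id")["lost_in_second"]
        assert not lost["l1"] and lost["l2"]
        assert summary["n_anchors_lost_in_second"] == 1
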