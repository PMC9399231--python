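"""ABC candidate construction, activity, contact and score normalization."""

import numpy as np
import pandas as pd
import pytest

from shearmap.abc_model import (
    CandidateElement,
    ContactModel,
    abc_scores,
    contact,
    make_candidate_regions,
    promoter_elements,
    quantify_activity,
)
from shearmap.intervals import Gene, GenomicInterval, Peak, merge_intervals, overlaps, resize_to_summit
from shearmap.io import CountMatrix

SAMPLES = ["LSS_rep1", "LSS_rep2", "ST_rep1", "ST_rep2"]
COND = {s: s.split("_")[0] for s in SAMPLES}


def peak(start, width, summit=None, name="p", chrom="chr1"):
    return Peak(
        GenomicInterval(chrom, start, start + width),
        width // 2 if summit is None else summit,
        0.0,
        name,
    )


def element(eid, start, end, activity, is_promoter=False, chrom="chr1"):
    return CandidateElement(
        eid, GenomicInterval(chrom, start, end), is_promoter, (eid,), activity=activity
    )


class TestMakeCandidateRegions:
    def test_no_overlap_keeps_all_at_width(self):
        peaks = [peak(10_000 * i + 1000, 600, name=f"p{i}") for i in range(10)]
        reads = {p.name: float(i) for i, p in enumerate(peaks)}
        out = make_candidate_regions(peaks, reads, top_n=10)
        assert len(out) == 10
        assert all(len(e.interval) == 250 for e in out)

    def test_overlapping_resized_regions_merge(self):
        peaks = [peak(1000, 600, name="a"), peak(1200, 600, name="b")]
        reads = {"a": 5.0, "b": 3.0}
        out = make_candidate_regions(peaks, reads, top_n=10)
        assert len(out) == 1
        assert len(out[0].interval) == 450
        assert out[0].source_peaks == ("a", "b")

    def test_top_n_and_blacklist(self):
        peaks = [peak(10_000 * i + 1000, 600, name=f"p{i}") for i in range(6)]
        reads = {f"p{i}": float(i) for i in range(6)}
        bl = [GenomicInterval("chr1", 51_200, 51_300)]  # overlaps p5's resize
        out = make_candidate_regions(peaks, reads, top_n=3, blacklist=bl)
        kept = {src for e in out for src in e.source_peaks}
        assert kept == {"p3", "p4"}  # top 3 were p5,p4,p3; p5 blacklisted

    def test_invalid_top_n(self):
        with pytest.raises(ValueError):
            make_candidate_regions([], {}, top_n=0)

    def test_matches_step_replay_oracle(self):
        rng = np.random.default_rng(30)
        peaks = []
        for i in range(2000):
            s = int(rng.integers(0, 5_000_000))
            w = int(rng.integers(200, 1_000))
            peaks.append(peak(s, w, summit=int(rng.integers(0, w)), name=f"p{i:04d}"))
        reads = {p.name: float(rng.integers(0, 500)) for p in peaks}
        bl = [GenomicInterval("chr1", s, s + 2_000) for s in rng.integers(0, 5_000_000, size=20)]
        out = make_candidate_regions(peaks, reads, top_n=800, blacklist=bl)

        # independent step-by-step replay
        resized = [(resize_to_summit(p, 250), p.name) for p in peaks]
        ranked = sorted(resized, key=lambda t: (-reads[t[1]], t[0].chrom, t[0].start))[:800]
        kept = [iv for iv, _ in ranked if not any(overlaps(iv, b) for b in bl)]
        expected = merge_intervals(kept)
        assert [e.interval for e in out] == expected


class TestQuantifyActivity:
    def matrix(self, values):
        ids = list(values)
        counts = np.array([values[i] for i in ids])
        return CountMatrix(ids, SAMPLES, counts, COND)

    def test_geometric_mean_identity_and_zero(self):
        els = [element("e1", 0, 250, 0.0), element("e2", 1000, 1250, 0.0)]
        atac = self.matrix({"e1": [100, 100, 0, 0], "e2": [0, 0, 50, 50]})
        k27 = self.matrix({"e1": [100, 100, 0, 0], "e2": [40, 60, 0, 0]})
        out = quantify_activity(els, atac, k27, "LSS")
        # equal rpm in both assays -> activity equals that rpm
        assert out[0].activity == pytest.approx(
            np.sqrt(out[0].atac_reads / 200 * 1e6 * out[0].h3k27ac_reads / 300 * 1e6)
        )
        e2 = quantify_activity(els, atac, k27, "ST")[1]
        assert e2.activity == 0.0  # zero H3K27ac under ST

    def test_missing_counts_error_names_element(self):
        els = [element("missing", 0, 250, 0.0)]
        atac = self.matrix({"e1": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="missing"):
            quantify_activity(els, atac, atac, "LSS")

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(31)
        els = [element(f"e{i}", i * 1000, i * 1000 + 250, 0.0) for i in range(20)]
        atac = self.matrix({f"e{i}": rng.integers(0, 500, size=4) for i in range(20)})
        k27 = self.matrix({f"e{i}": rng.integers(0, 500, size=4) for i in range(20)})
        out = quantify_activity(els, atac, k27, "LSS")
        a_sum = np.array([atac.counts[i, :2].sum() for i in range(20)], dtype=float)
        k_sum = np.array([k27.counts[i, :2].sum() for i in range(20)], dtype=float)
        expect = np.sqrt(a_sum / a_sum.sum() * 1e6 * k_sum / k_sum.sum() * 1e6)
        assert np.allclose([e.activity for e in out], expect, rtol=1e-12)


class TestContact:
    def gene(self, tss=1_000_000):
        return Gene("g", "g", GenomicInterval("chr1", tss, tss + 5_000), "+")

    def test_forced_arithmetic(self):
        el = GenomicInterval("chr1", 1_004_875, 1_005_125)  # midpoint 5000 away
        assert contact(el, self.gene()) == pytest.approx(1 / 10_000, rel=1e-12)

    def test_doubling_distance_halves_contact(self):
        g = self.gene()
        c1 = contact(GenomicInterval("chr1", 1_500_000, 1_500_250), g)
        c2 = contact(GenomicInterval("chr1", 2_000_250, 2_000_500), g)
        assert c1 / c2 == pytest.approx(2.0, rel=0.05)

    def test_cross_chromosome_contact_zero(self):
        el = GenomicInterval("chr2", 0, 250)
        assert contact(el, self.gene()) == 0.0

    def test_observed_contacts_floored_at_power_law(self):
        hic = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "bin1": [100, 200, 300],
             "bin2": [150, 260, 350], "count": [10, 10, 1000]}
        )
        model = ContactModel(hic=hic, resolution=1000)
        # boosted pair exceeds power law
        boosted = model.contact("chr1", 300_500, "chr1", 350_500)
        assert boosted > model.powerlaw(50_000)
        # unobserved pair falls back to power law
        assert model.contact("chr1", 0, "chr1", 50_000) == model.powerlaw(50_000)


class TestAbcScores:
    def gene(self, tss=500_000):
        return Gene("g1", "g1", GenomicInterval("chr1", tss, tss + 5_000), "+")

    def test_single_element_scores_one(self):
        g = self.gene()
        els = [element("e1", 450_000, 450_250, 10.0)]
        out = abc_scores(g, els)
        assert out.iloc[0]["score"] == pytest.approx(1.0)

    def test_products_one_three_split(self):
        g = self.gene()
        d = 100_000
        c = 1.0 / (d + 5_000)
        els = [
            element("e1", g.tss - d - 125, g.tss - d + 125, 1.0 / c),
            element("e2", g.tss + d - 125, g.tss + d + 125, 3.0 / c),
        ]
        out = abc_scores(g, els).set_index("element_id")
        assert out.loc["e1", "score"] == pytest.approx(0.25, rel=1e-9)
        assert out.loc["e2", "score"] == pytest.approx(0.75, rel=1e-9)

    def test_promoter_element_gets_max_window_contact(self):
        g = self.gene()
        els = promoter_elements([g])
        els = [
            CandidateElement(e.element_id, e.interval, True, e.source_peaks, activity=5.0)
            for e in els
        ] + [element("near", g.tss - 10_125, g.tss - 9_875, 5.0)]
        out = abc_scores(g, els).set_index("element_id")
        assert out.loc["prom_g1", "contact"] == out["contact"].max()

    def test_zero_activity_all_scores_zero(self):
        g = self.gene()
        els = [element("e1", 450_000, 450_250, 0.0)]
        out = abc_scores(g, els)
        assert (out["score"] == 0).all() and not out["passes"].any()

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            abc_scores(self.gene(), [element("e1", 0, 250, 1.0)], threshold=1.5)

    def test_monotonicity_and_scale_invariance(self):
        rng = np.random.default_rng(32)
        g = self.gene()
        els = [
            element(f"e{i}", int(p), int(p) + 250, float(rng.uniform(1, 10)))
            for i, p in enumerate(rng.integers(100_000, 900_000, size=8))
        ]
        base = abc_scores(g, els).set_index("element_id")["score"]
        bumped = [
            CandidateElement(e.element_id, e.interval, e.is_promoter, e.source_peaks,
                             activity=e.activity * (3.0 if e.element_id == "e0" else 1.0))
            for e in els
        ]
        up = abc_scores(g, bumped).set_index("element_id")["score"]
        assert up["e0"] > base["e0"]
        for eid in base.index.drop("e0"):
            assert up[eid] < base[eid]
        scaled = [
            CandidateElement(e.element_id, e.interval, e.is_promoter, e.source_peaks,
                             activity=e.activity * 7.5)
            for e in els
        ]
        assert np.allclose(
            abc_scores(g, scaled).set_index("element_id")["score"], base, rtol=1e-12
        )
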