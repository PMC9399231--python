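"""Synthetic two-condition toy dataset with planted ground truth.

Emulates the statistical structure of a flow-vs-static endothelial
epigenomics study on a 10 Mb single-chromosome toy genome: candidate
accessible regions with negative-binomial replicate counts, a subset of
planted enhancers whose accessibility, H3K27ac, KLF4 and BRG1 signal shift
between conditions (LSS vs ST), a KLF-like motif embedded in the sequence
of opening enhancers, gene expression driven by planted enhancer-gene
links, a distance-decaying HiChIP contact map with boosted planted
enhancer-promoter loops, and SNPs placed inside a subset of enhancers.

Everything is a pure function of the config (identical seed, identical
bytes on disk), and the planted truth tables are written alongside the
data so every downstream stage can be scored against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as smio
from .intervals import Gene, GenomicInterval, Peak
from .io import CountMatrix, SNPRecord
from .motifs import PWM

CONDITIONS = ("LSS", "ST")

#: synthetic KLF-like GC-rich 10-mer used for planting (no external motif db)
KLF_LIKE_CONSENSUS = "GGGGTGGGGC"


def klf_like_pwm(dominant: float = 0.85) -> PWM:
    probs = np.full((4, len(KLF_LIKE_CONSENSUS)), (1 - dominant) / 3)
    for j, base in enumerate(KLF_LIKE_CONSENSUS):
        probs["ACGT".index(base), j] = dominant
    return PWM(name="KLF_like", probs=probs)


@dataclass
class SynthConfig:
    """Parameters of the synthetic study. Defaults are the study conditions
    every acceptance property is evaluated under."""

    genome_length: int = 10_000_000
    chrom: str = "chr1"
    n_genes: int = 120
    n_candidate_regions: int = 800
    n_planted_enhancers: int = 150
    frac_dar_up: float = 0.5
    dar_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    mean_count: float = 200.0
    replicates: int = 3
    contact_gamma: float = 1.0
    loop_boost: float = 8.0
    seed: int = 0
    # generator conventions (units: bp unless noted)
    region_width: int = 500
    contact_d0: int = 5_000
    resolution: int = 1_000
    min_loop_distance: int = 10_000
    max_loop_distance: int = 1_000_000
    enhancer_tss_min: int = 10_000
    enhancer_tss_max: int = 80_000
    background_tss_exclusion: int = 0
    effect_jitter: float = 0.4  # per-region |log2FC| spread: U[1-j, 1+j] * dar_log2fc
    hichip_rate: float = 150_000.0  # per-replicate Poisson rate scale
    hichip_max_span: int = 2_000_000
    promoter_mean: float = 2000.0  # ATAC and H3K27ac at promoter features
    inactive_k27_mean: float = 30.0
    enhancer_k27_mean: float = 300.0
    chip_bound_mean: float = 150.0  # KLF4/BRG1 at bound regions
    chip_unbound_mean: float = 30.0
    rna_base_mean: float = 200.0
    rna_lognorm_sigma: float = 0.4
    link_weight_low: float = 0.8
    link_weight_high: float = 1.2
    motif_decoy_frac: float = 0.05
    n_snps_in_enhancers: int = 22
    n_decoy_snps: int = 30

    def __post_init__(self) -> None:
        for name in ("genome_length", "n_genes", "n_candidate_regions",
                     "n_planted_enhancers", "replicates", "region_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0.0 <= self.frac_dar_up <= 1.0):
            raise ValueError("frac_dar_up must lie in [0, 1]")
        if self.n_planted_enhancers > self.n_candidate_regions:
            raise ValueError("more planted enhancers than candidate regions")
        # rough feasibility: every region needs width + 1 kb clearance
        if self.n_candidate_regions * (self.region_width + 1000) > self.genome_length:
            raise ValueError("candidate regions exceed genome length")


@dataclass
class SyntheticTruth:
    """Planted ground truth: the acceptance oracle for every stage."""

    planted_dar: dict[str, int]  # region_id -> +1 (opens with LSS) / -1
    planted_motif_regions: set[str]
    enhancer_gene_links: dict[str, tuple[str, float]]  # region_id -> (gene_id, effect)
    planted_loops: set[tuple[int, int]]  # (bin1, bin2), bin1 < bin2
    true_deg: dict[str, float]  # gene_id -> true log2 fold-change
    loop_of_link: dict[str, tuple[int, int]] = field(default_factory=dict)
    planted_lfc: dict[str, float] = field(default_factory=dict)  # signed true log2FC

    def up_regions(self) -> set[str]:
        return {r for r, s in self.planted_dar.items() if s > 0}

    def down_regions(self) -> set[str]:
        return {r for r, s in self.planted_dar.items() if s < 0}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws under Var = mu + dispersion * mu^2 (zero mean -> zero count)."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = n / (n + mean[pos])
    out[pos] = rng.negative_binomial(n, p, size=int(pos.sum()))
    return out


def generate_null_counts(
    n_features: int,
    replicates: int,
    mean: float,
    dispersion: float,
    seed: int,
    prefix: str = "feature",
) -> CountMatrix:
    """Global-null count matrix: both conditions share NB(mean, dispersion)
    marginals and no feature carries a true effect (type-I-error harness)."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    samples = [f"{c}_rep{i+1}" for c in CONDITIONS for i in range(replicates)]
    means = np.full((n_features, len(samples)), float(mean))
    counts = _nb_draw(rng, means, dispersion)
    width = len(str(n_features))
    return CountMatrix(
        [f"{prefix}_{i+1:0{width}d}" for i in range(n_features)],
        samples,
        counts,
        {s: s.split("_")[0] for s in samples},
    )


# ---------------------------------------------------------------------------
# placement


def _place_genes(cfg: SynthConfig, rng: np.random.Generator) -> list[Gene]:
    spacing = cfg.genome_length / (cfg.n_genes + 1)
    genes: list[Gene] = []
    for i in range(cfg.n_genes):
        tss = int((i + 1) * spacing + rng.uniform(-0.2, 0.2) * spacing)
        tss = int(np.clip(tss, 20_000, cfg.genome_length - 20_000))
        strand = "+" if rng.random() < 0.5 else "-"
        body = int(rng.integers(2_000, 10_000))
        if strand == "+":
            iv = GenomicInterval(cfg.chrom, tss, min(tss + body, cfg.genome_length))
        else:
            iv = GenomicInterval(cfg.chrom, max(tss + 1 - body, 0), tss + 1)
        gid = f"G{i+1:04d}"
        genes.append(Gene(gid, f"SYN{i+1}", iv, strand))
    return genes


def _place_regions(
    cfg: SynthConfig, rng: np.random.Generator, genes: list[Gene]
) -> tuple[list[dict], list[dict]]:
    """Place planted enhancers near their target TSS and background regions
    away from every TSS. Returns (planted records, background records) with
    midpoints; ids are assigned later in coordinate order."""
    tss = np.array(sorted(g.tss for g in genes))
    tss_of_gene = {g.gene_id: g.tss for g in genes}
    half = cfg.region_width // 2
    occupied: list[tuple[int, int]] = []  # sorted midpoint spans

    def clashes(mid: int) -> bool:
        for lo, hi in occupied:
            if mid - cfg.region_width - 1000 < hi and mid + cfg.region_width + 1000 > lo:
                return True
        return False

    gene_cycle = [genes[i] for i in rng.permutation(len(genes))]
    planted: list[dict] = []
    for k in range(cfg.n_planted_enhancers):
        target = gene_cycle[k % len(gene_cycle)]
        placed = False
        for _ in range(200):
            d = int(rng.integers(cfg.enhancer_tss_min, cfg.enhancer_tss_max + 1))
            side = 1 if rng.random() < 0.5 else -1
            mid = tss_of_gene[target.gene_id] + side * d
            if not (half + 1000 < mid < cfg.genome_length - half - 1000):
                continue
            # the target must remain the nearest TSS so nearest-gene pairing
            # coincides with the planted link
            j = np.searchsorted(tss, mid)
            near = min(
                (abs(mid - t) for t in tss[max(0, j - 2): j + 2]), default=d
            )
            if near < d:
                continue
            if clashes(mid):
                continue
            planted.append({"mid": mid, "target": target.gene_id, "tss_distance": side * d})
            occupied.append((mid - half, mid + half))
            placed = True
            break
        if not placed:
            raise ValueError(
                "infeasible placement: could not position a planted enhancer; "
                "reduce n_planted_enhancers or enlarge the genome"
            )
    n_bg = cfg.n_candidate_regions - cfg.n_planted_enhancers
    background: list[dict] = []
    tries = 0
    while len(background) < n_bg:
        tries += 1
        if tries > 200 * n_bg:
            raise ValueError("infeasible placement: background regions do not fit")
        mid = int(rng.integers(half + 1000, cfg.genome_length - half - 1000))
        if cfg.background_tss_exclusion > 0:
            j = np.searchsorted(tss, mid)
            near = min((abs(mid - t) for t in tss[max(0, j - 1): j + 1]), default=mid)
            if near < cfg.background_tss_exclusion:
                continue
        if clashes(mid):
            continue
        background.append({"mid": mid})
        occupied.append((mid - half, mid + half))
    return planted, background


# ---------------------------------------------------------------------------
# main generator


def generate_dataset(
    cfg: SynthConfig, outdir: str | Path
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Write the full synthetic dataset to ``outdir``; return paths + truth.

    Files: candidate regions (narrowPeak), gene TSV, ATAC / H3K27ac / KLF4 /
    BRG1 / RNA count TSVs, region sequences (FASTA), the planted KLF-like
    PWM, per-condition-per-replicate HiChIP BEDPE, SNP TSV, truth tables,
    and a manifest JSON recording the config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(cfg.seed).spawn(8)
    rng_place, rng_counts, rng_rna, rng_seq, rng_hichip, rng_links, rng_snps, _ = [
        np.random.default_rng(s) for s in streams
    ]

    genes = _place_genes(cfg, rng_place)
    planted_rec, background_rec = _place_regions(cfg, rng_place, genes)

    # assign ids in coordinate order
    all_rec = [dict(r, planted=True) for r in planted_rec] + [
        dict(r, planted=False) for r in background_rec
    ]
    all_rec.sort(key=lambda r: r["mid"])
    half = cfg.region_width // 2
    peaks: list[Peak] = []
    for i, rec in enumerate(all_rec):
        rid = f"region_{i+1:04d}"
        rec["id"] = rid
        start = rec["mid"] - half
        peaks.append(
            Peak(
                GenomicInterval(cfg.chrom, start, start + cfg.region_width),
                half,
                float(cfg.mean_count),
                rid,
            )
        )

    planted_ids = [r["id"] for r in all_rec if r["planted"]]
    n_up = int(round(cfg.frac_dar_up * len(planted_ids)))
    up_ids = set(rng_links.permutation(planted_ids)[:n_up].tolist())
    planted_dar = {rid: (1 if rid in up_ids else -1) for rid in planted_ids}

    # per-region true effect sizes (heterogeneous magnitudes around
    # dar_log2fc) and enhancer -> gene links with signed effect weights
    planted_lfc: dict[str, float] = {}
    enhancer_gene_links: dict[str, tuple[str, float]] = {}
    for rec in all_rec:
        if not rec["planted"]:
            continue
        jitter = rng_links.uniform(1.0 - cfg.effect_jitter, 1.0 + cfg.effect_jitter)
        lfc = planted_dar[rec["id"]] * cfg.dar_log2fc * jitter
        planted_lfc[rec["id"]] = lfc
        w = rng_links.uniform(cfg.link_weight_low, cfg.link_weight_high)
        enhancer_gene_links[rec["id"]] = (rec["target"], w * lfc)

    # motif-bearing regions: every opening enhancer plus a small decoy
    # fraction of the background
    bg_ids = [r["id"] for r in all_rec if not r["planted"]]
    n_decoy = int(round(cfg.motif_decoy_frac * len(bg_ids)))
    decoy_ids = set(rng_links.permutation(bg_ids)[:n_decoy].tolist())
    planted_motif_regions = set(up_ids) | decoy_ids

    # ------------------------------------------------------------------
    # count matrices; the active condition of a planted enhancer carries
    # the boosted signal so gains (LSS) and losses (ST-active) are
    # symmetric in magnitude
    samples = [f"{c}_rep{i+1}" for c in CONDITIONS for i in range(cfg.replicates)]
    condition_of = {s: s.split("_")[0] for s in samples}
    region_ids = [p.name for p in peaks]
    prom_ids = [f"prom_{g.gene_id}" for g in genes]
    feature_ids = region_ids + prom_ids
    rboost = {rid: 2.0 ** abs(lfc) for rid, lfc in planted_lfc.items()}

    def region_means(base: float, lss: dict[str, float], st: dict[str, float],
                     prom: float) -> dict[str, np.ndarray]:
        per_cond = {}
        for cond in CONDITIONS:
            override = lss if cond == "LSS" else st
            vals = [override.get(rid, base) for rid in region_ids]
            vals += [prom] * len(prom_ids)
            per_cond[cond] = np.array(vals)
        return per_cond

    mc = cfg.mean_count
    atac_means = region_means(
        mc,
        lss={rid: mc * rboost[rid] for rid in up_ids},
        st={rid: mc * rboost[rid] for rid in planted_ids if rid not in up_ids},
        prom=cfg.promoter_mean,
    )
    k27_means = region_means(
        cfg.inactive_k27_mean,
        lss={rid: cfg.enhancer_k27_mean * (rboost[rid] if rid in up_ids else 1.0)
             for rid in planted_ids},
        st={rid: cfg.enhancer_k27_mean * (1.0 if rid in up_ids else rboost[rid])
            for rid in planted_ids},
        prom=cfg.promoter_mean,
    )
    klf4_means = region_means(
        cfg.chip_unbound_mean,
        lss={rid: cfg.chip_bound_mean * (rboost.get(rid, 1.0) if rid in up_ids else 1.0)
             for rid in planted_motif_regions},
        st={rid: cfg.chip_bound_mean for rid in planted_motif_regions},
        prom=cfg.chip_unbound_mean,
    )
    brg1_means = region_means(
        cfg.chip_unbound_mean,
        lss={rid: cfg.chip_bound_mean * (rboost[rid] if rid in up_ids else 1.0)
             for rid in planted_ids},
        st={rid: cfg.chip_bound_mean * (1.0 if rid in up_ids else rboost[rid])
            for rid in planted_ids},
        prom=2 * cfg.chip_unbound_mean,
    )

    def draw_matrix(per_cond: dict[str, np.ndarray]) -> CountMatrix:
        cols = [
            _nb_draw(rng_counts, per_cond[condition_of[s]], cfg.nb_dispersion)
            for s in samples
        ]
        return CountMatrix(feature_ids, samples, np.column_stack(cols), dict(condition_of))

    atac = draw_matrix(atac_means)
    k27 = draw_matrix(k27_means)
    klf4 = draw_matrix(klf4_means)
    brg1 = draw_matrix(brg1_means)

    # RNA: linked-gene means shift by the summed enhancer effects under LSS
    gene_effect: dict[str, float] = {g.gene_id: 0.0 for g in genes}
    for rid, (gid, eff) in enhancer_gene_links.items():
        gene_effect[gid] += eff
    true_deg = {g: e for g, e in gene_effect.items() if e != 0.0}
    rna_base = cfg.rna_base_mean * np.exp(
        rng_rna.normal(0.0, cfg.rna_lognorm_sigma, size=cfg.n_genes)
    )
    rna_cols = []
    for s in samples:
        fac = (
            np.array([2.0 ** gene_effect[g.gene_id] for g in genes])
            if condition_of[s] == "LSS"
            else np.ones(cfg.n_genes)
        )
        rna_cols.append(_nb_draw(rng_rna, rna_base * fac, cfg.nb_dispersion))
    rna = CountMatrix(
        [g.gene_id for g in genes], samples, np.column_stack(rna_cols), dict(condition_of)
    )

    # ------------------------------------------------------------------
    # sequences: uniform A/C/G/T with the motif consensus at the summit of
    # motif-bearing regions
    pwm = klf_like_pwm()
    seqs: dict[str, str] = {}
    for p in peaks:
        letters = rng_seq.integers(0, 4, size=len(p.interval))
        seq = "".join("ACGT"[i] for i in letters)
        if p.name in planted_motif_regions:
            pos = p.summit_offset - len(KLF_LIKE_CONSENSUS) // 2
            seq = seq[:pos] + KLF_LIKE_CONSENSUS + seq[pos + len(KLF_LIKE_CONSENSUS):]
        seqs[p.name] = seq

    # ------------------------------------------------------------------
    # HiChIP: Poisson tags between peak-summit and TSS bins with a
    # (d + d0)^(-gamma) decay; planted enhancer-promoter bin pairs are
    # boosted under LSS
    res = cfg.resolution
    summit_bins = {p.name: p.summit // res for p in peaks}
    tss_bins = {g.gene_id: g.tss // res for g in genes}
    active_bins = np.array(sorted(set(summit_bins.values()) | set(tss_bins.values())))
    planted_loops: set[tuple[int, int]] = set()
    loop_of_link: dict[str, tuple[int, int]] = {}
    loop_active_cond: dict[tuple[int, int], str] = {}
    for rid, (gid, _) in enhancer_gene_links.items():
        b1, b2 = sorted((summit_bins[rid], tss_bins[gid]))
        dist = (b2 - b1) * res
        if cfg.min_loop_distance <= dist <= cfg.max_loop_distance:
            planted_loops.add((b1, b2))
            loop_of_link[rid] = (b1, b2)
            # a loop is boosted in the condition its enhancer is active in:
            # opening enhancers gain their loop under LSS, closing ones keep
            # theirs under ST (loops "lost with LSS")
            loop_active_cond[(b1, b2)] = "LSS" if planted_dar[rid] > 0 else "ST"

    pos = active_bins * res
    idx1, idx2 = [], []
    max_span = cfg.hichip_max_span
    for i in range(len(active_bins)):
        j_hi = np.searchsorted(pos, pos[i] + max_span, side="right")
        for j in range(i + 1, j_hi):
            if pos[j] - pos[i] >= res:
                idx1.append(i)
                idx2.append(j)
    idx1 = np.array(idx1)
    idx2 = np.array(idx2)
    dist = pos[idx2] - pos[idx1]
    base_rate = cfg.hichip_rate * (dist + cfg.contact_d0) ** (-cfg.contact_gamma)
    pair_keys = list(zip(active_bins[idx1].tolist(), active_bins[idx2].tolist()))
    hichip_paths: dict[str, Path] = {}
    for cond in CONDITIONS:
        boosted = np.array([loop_active_cond.get(k) == cond for k in pair_keys])
        rate = base_rate * np.where(boosted, cfg.loop_boost, 1.0)
        for rep in range(1, cfg.replicates + 1):
            counts = rng_hichip.poisson(rate)
            nz = counts > 0
            df = pd.DataFrame(
                {
                    "chrom1": cfg.chrom,
                    "start1": active_bins[idx1[nz]] * res,
                    "end1": active_bins[idx1[nz]] * res + res,
                    "chrom2": cfg.chrom,
                    "start2": active_bins[idx2[nz]] * res,
                    "end2": active_bins[idx2[nz]] * res + res,
                    "name": ".",
                    "count": counts[nz],
                }
            )
            path = outdir / f"hichip_{cond}_rep{rep}.bedpe"
            smio.write_loops(df, path)
            hichip_paths[f"hichip_{cond}_rep{rep}"] = path

    # ------------------------------------------------------------------
    # SNPs: some inside linked planted enhancers, decoys in open genome
    linked_ids = sorted(enhancer_gene_links)
    chosen = rng_snps.permutation(linked_ids)[: cfg.n_snps_in_enhancers]
    peak_by_id = {p.name: p for p in peaks}
    snps: list[SNPRecord] = []
    for i, rid in enumerate(chosen):
        p = peak_by_id[rid]
        # near the summit, as a motif-disrupting regulatory variant would be
        offset = p.summit_offset + int(rng_snps.integers(-100, 101))
        offset = int(np.clip(offset, 0, len(p.interval) - 1))
        snps.append(SNPRecord(f"rs{9000000 + i}", cfg.chrom, p.interval.start + offset))
    spans = sorted((p.interval.start, p.interval.end) for p in peaks)
    starts = np.array([s for s, _ in spans])
    ends = np.array([e for _, e in spans])
    n_dec = 0
    while n_dec < cfg.n_decoy_snps:
        posn = int(rng_snps.integers(0, cfg.genome_length))
        j = np.searchsorted(starts, posn, side="right") - 1
        inside = j >= 0 and posn < ends[j]
        if inside:
            continue
        snps.append(SNPRecord(f"rs{8000000 + n_dec}", cfg.chrom, posn))
        n_dec += 1

    # ------------------------------------------------------------------
    # write everything
    paths: dict[str, Path] = dict(hichip_paths)

    def _p(key: str, name: str) -> Path:
        paths[key] = outdir / name
        return paths[key]

    smio.write_regions(peaks, _p("regions", "regions.narrowPeak"), "narrowPeak")
    smio.write_genes(genes, _p("genes", "genes.tsv"))
    smio.write_counts(atac, _p("atac", "atac_counts.tsv"))
    smio.write_counts(k27, _p("h3k27ac", "h3k27ac_counts.tsv"))
    smio.write_counts(klf4, _p("klf4", "klf4_counts.tsv"))
    smio.write_counts(brg1, _p("brg1", "brg1_counts.tsv"))
    smio.write_counts(rna, _p("rna", "rna_counts.tsv"))
    smio.write_fasta(seqs, _p("sequences", "sequences.fa"))
    smio.write_pwm(pwm, _p("pwm", "klf_like.pwm"))
    smio.write_snps(snps, _p("snps", "snps.tsv"))

    truth = SyntheticTruth(
        planted_dar=planted_dar,
        planted_lfc=planted_lfc,
        planted_motif_regions=planted_motif_regions,
        enhancer_gene_links=enhancer_gene_links,
        planted_loops=planted_loops,
        true_deg=true_deg,
        loop_of_link=loop_of_link,
    )
    write_truth(truth, outdir, paths)

    manifest = {"config": asdict(cfg), "format_version": 1}
    with open(_p("manifest", "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths, truth


# ---------------------------------------------------------------------------
# truth round trip


def write_truth(truth: SyntheticTruth, outdir: str | Path, paths: Optional[dict] = None) -> None:
    outdir = Path(outdir)
    if paths is None:
        paths = {}

    def _p(key: str, name: str) -> Path:
        paths[key] = outdir / name
        return paths[key]

    pd.DataFrame(
        sorted(
            (r, s, truth.planted_lfc.get(r, float("nan")))
            for r, s in truth.planted_dar.items()
        ),
        columns=["region_id", "sign", "log2fc"],
    ).to_csv(_p("truth_dar", "truth_dar.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {"region_id": sorted(truth.planted_motif_regions)}
    ).to_csv(_p("truth_motifs", "truth_motifs.tsv"), sep="\t", index=False)
    links = pd.DataFrame(
        sorted((r, g, e) for r, (g, e) in truth.enhancer_gene_links.items()),
        columns=["region_id", "gene_id", "effect"],
    )
    loop1 = [truth.loop_of_link.get(r, (-1, -1))[0] for r in links["region_id"]]
    loop2 = [truth.loop_of_link.get(r, (-1, -1))[1] for r in links["region_id"]]
    links["loop_bin1"], links["loop_bin2"] = loop1, loop2
    links.to_csv(_p("truth_links", "truth_links.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.planted_loops), columns=["bin1", "bin2"]
    ).to_csv(_p("truth_loops", "truth_loops.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.true_deg.items()), columns=["gene_id", "log2fc"]
    ).to_csv(_p("truth_deg", "truth_deg.tsv"), sep="\t", index=False)


def read_truth(outdir: str | Path) -> SyntheticTruth:
    outdir = Path(outdir)
    dar = pd.read_csv(outdir / "truth_dar.tsv", sep="\t")
    motifs = pd.read_csv(outdir / "truth_motifs.tsv", sep="\t")
    links = pd.read_csv(outdir / "truth_links.tsv", sep="\t")
    loops = pd.read_csv(outdir / "truth_loops.tsv", sep="\t")
    deg = pd.read_csv(outdir / "truth_deg.tsv", sep="\t")
    loop_of_link = {
        r.region_id: (int(r.loop_bin1), int(r.loop_bin2))
        for r in links.itertuples(index=False)
        if r.loop_bin1 >= 0
    }
    return SyntheticTruth(
        planted_dar={r.region_id: int(r.sign) for r in dar.itertuples(index=False)},
        planted_lfc=(
            {r.region_id: float(r.log2fc) for r in dar.itertuples(index=False)}
            if "log2fc" in dar.columns
            else {}
        ),
        planted_motif_regions=set(motifs["region_id"]),
        enhancer_gene_links={
            r.region_id: (r.gene_id, float(r.effect)) for r in links.itertuples(index=False)
        },
        planted_loops={(int(r.bin1), int(r.bin2)) for r in loops.itertuples(index=False)},
        true_deg={r.gene_id: float(r.log2fc) for r in deg.itertuples(index=False)},
        loop_of_link=loop_of_link,
    )
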