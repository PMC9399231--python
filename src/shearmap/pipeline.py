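"""End-to-end orchestration of the enhancer-landscape analysis.

Each stage reads the plain-text inputs written by the simulator (or by the
user), runs one analysis layer, and writes versioned TSV/JSON outputs into
the run directory. ``run_all`` chains every stage and assembles a markdown
report — the synthetic analogue of a full flow-vs-static study: DAR and
DEG tables, peak annotation, motif enrichment, accessibility-expression
correlation, KLF4/BRG1 co-occupancy, ABC enhancer-gene predictions,
HiChIP loops with classification and differential status, KLF4-at-anchor
integration, and SNP-to-target-gene mapping.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import abc_model, annotate, differential, loops as loops_mod, motifs as motifs_mod
from . import io as smio
from . import synthetic
from .intervals import GenomicInterval
from .io import CountMatrix

CONDITIONS = ("LSS", "ST")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one run. ``data_dir`` holds the inputs (the
    simulator's output layout); ``outdir`` receives all results."""

    data_dir: str = "data"
    outdir: str = "results"
    seed: int = 1
    alpha: float = 0.1  # BH-adjusted significance for DAR/DEG/DBR/loops
    loop_q: float = 0.01  # loop-calling q-value threshold
    abc_threshold: float = 0.02
    promoter_bp: int = 3000
    resolution: int = 1000
    min_loop_distance: int = 1000
    replicates: int = 3
    condition_a: str = "LSS"
    condition_b: str = "ST"
    n_motif_decoys: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.loop_q < 1):
            raise ValueError("alpha and loop_q must lie in (0, 1)")
        if not (0 < self.abc_threshold < 1):
            raise ValueError("abc_threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def input_path(self, name: str) -> Path:
        p = Path(self.data_dir) / name
        if not p.exists():
            raise FileNotFoundError(f"missing input {name!r}: expected at {p} (check data_dir)")
        return p


def _log(msg: str) -> None:
    print(f"[shearmap] {msg}", file=sys.stderr)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Pipeline:
    """Stage runner. Stages are idempotent and re-read their own inputs so
    they can be invoked individually from the CLI."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    # -- inputs ---------------------------------------------------------

    def _peaks(self):
        return smio.read_regions(self.cfg.input_path("regions.narrowPeak"), "narrowPeak")

    def _genes(self):
        return smio.read_genes(self.cfg.input_path("genes.tsv"))

    def _counts(self, name: str) -> CountMatrix:
        return smio.read_counts(self.cfg.input_path(name))

    def _results(self, name: str) -> pd.DataFrame:
        p = self.outdir / name
        if not p.exists():
            raise FileNotFoundError(f"stage output {name!r} missing; run the earlier stage first")
        return pd.read_csv(p, sep="\t")

    # -- stages ---------------------------------------------------------

    def simulate(self, synth_config: Optional[synthetic.SynthConfig] = None):
        cfg = synth_config or synthetic.SynthConfig(seed=self.cfg.seed)
        t0 = time.time()
        paths, truth = synthetic.generate_dataset(cfg, self.cfg.data_dir)
        _log(f"simulate: wrote {len(paths)} files to {self.cfg.data_dir} "
             f"({time.time()-t0:.1f}s)")
        return paths, truth

    def _differential_stage(self, counts_name: str, out_name: str) -> pd.DataFrame:
        m = self._counts(counts_name)
        res = differential.nb_wald_test(
            m, alpha_sig=self.cfg.alpha,
            condition_a=self.cfg.condition_a, condition_b=self.cfg.condition_b,
        )
        differential.write_results(res, self.outdir / out_name)
        n_up = int((res["significant"] & (res["log2fc"] > 0)).sum())
        n_dn = int((res["significant"] & (res["log2fc"] < 0)).sum())
        _log(f"{out_name}: {n_up} up / {n_dn} down at padj < {self.cfg.alpha}")
        return res

    def dar(self) -> pd.DataFrame:
        return self._differential_stage("atac_counts.tsv", "dar_results.tsv")

    def deg(self) -> pd.DataFrame:
        return self._differential_stage("rna_counts.tsv", "deg_results.tsv")

    def dbr(self) -> dict[str, pd.DataFrame]:
        return {
            "klf4": self._differential_stage("klf4_counts.tsv", "klf4_dbr_results.tsv"),
            "brg1": self._differential_stage("brg1_counts.tsv", "brg1_dbr_results.tsv"),
        }

    def motifs(self) -> pd.DataFrame:
        """Enrichment of the study PWM (plus shuffled-column decoys) in
        opening DARs against accessible-but-not-differential regions."""
        dar = self._results("dar_results.tsv")
        seqs = smio.read_fasta(self.cfg.input_path("sequences.fa"))
        pwm = smio.read_pwm(self.cfg.input_path("klf_like.pwm"))
        rng = np.random.default_rng(self.cfg.seed + 101)
        pwms = [pwm] + [
            motifs_mod.shuffle_pwm_columns(pwm, rng, tag=f"shuffled{i+1}")
            for i in range(self.cfg.n_motif_decoys)
        ]
        region_ids = [f for f in dar["feature_id"] if f in seqs]
        dar_idx = dar.set_index("feature_id")
        fg = [r for r in region_ids
              if dar_idx.loc[r, "significant"] and dar_idx.loc[r, "log2fc"] > 0]
        bg = [r for r in region_ids if not dar_idx.loc[r, "significant"]]
        table = motifs_mod.motif_enrichment(fg, bg, seqs, pwms)
        table.to_csv(self.outdir / "motif_enrichment.tsv", sep="\t", index=False)
        _log(f"motifs: top motif {table.iloc[0]['motif']} "
             f"p={table.iloc[0]['binom_p']:.3g} over {len(fg)} opening DARs")
        return table

    def annotate(self) -> dict:
        peaks = self._peaks()
        genes = self._genes()
        dar = self._results("dar_results.tsv")
        deg = self._results("deg_results.tsv")
        sig_ids = set(dar[dar["significant"]]["feature_id"])
        dar_peaks = [p for p in peaks if p.name in sig_ids]
        ann, tally = annotate.annotate_peaks(
            dar_peaks, genes, promoter_bp=self.cfg.promoter_bp
        )
        ann.to_csv(self.outdir / "dar_annotation.tsv", sep="\t", index=False)
        hist = annotate.distance_distribution(dar_peaks, genes)
        hist.to_csv(self.outdir / "dar_distance_histogram.tsv", sep="\t", index=False)
        r, p, pairs = annotate.dar_deg_correlation(dar, peaks, deg, genes)
        pairs.to_csv(self.outdir / "dar_deg_pairs.tsv", sep="\t", index=False)

        klf4 = self._results("klf4_dbr_results.tsv").set_index("feature_id")
        brg1 = self._results("brg1_dbr_results.tsv").set_index("feature_id")
        peak_by_id = {pk.name: pk for pk in peaks}
        klf4_dbr = [peak_by_id[i].interval for i in klf4[klf4["significant"]].index
                    if i in peak_by_id]
        brg1_dbr = [peak_by_id[i].interval for i in brg1[brg1["significant"]].index
                    if i in peak_by_id]
        dar_idx = dar.set_index("feature_id")
        up_peaks = [p for p in dar_peaks if dar_idx.loc[p.name, "log2fc"] > 0]
        summary, flags = annotate.cooccupancy(
            up_peaks, klf4_dbr, brg1_dbr,
            klf4_log2fc=dict(klf4["log2fc"]),
            atac_log2fc=dict(dar_idx["log2fc"]),
        )
        flags.to_csv(self.outdir / "cooccupancy_flags.tsv", sep="\t", index=False)
        out = {
            "category_tally": tally,
            "dar_deg_r": r,
            "dar_deg_p": p,
            "n_dar_deg_pairs": len(pairs),
            "cooccupancy": {
                "n_dar": summary.n_dar,
                "n_both": summary.n_both,
                "n_klf4_only": summary.n_klf4_only,
                "n_brg1_only": summary.n_brg1_only,
                "n_neither": summary.n_neither,
                "fractions": summary.fractions,
                "klf4_accessibility_r": summary.klf4_accessibility_r,
            },
        }
        _write_json(out, self.outdir / "annotation_summary.json")
        _log(f"annotate: DAR-DEG r={r:.3f} (n={len(pairs)}), "
             f"co-occupied fraction={summary.fractions['both']:.2f}")
        return out

    # -- ABC ------------------------------------------------------------

    def _build_elements(self):
        peaks = self._peaks()
        genes = self._genes()
        atac = self._counts("atac_counts.tsv")
        total_reads = dict(zip(atac.feature_ids, np.asarray(atac.counts).sum(axis=1)))
        reads = {p.name: float(total_reads.get(p.name, 0.0)) for p in peaks}
        elements = abc_model.make_candidate_regions(peaks, reads)
        elements += abc_model.promoter_elements(genes)
        return peaks, genes, atac, elements

    def _contact_model(self, condition: str) -> abc_model.ContactModel:
        """Contact from the condition's pooled HiChIP map when present
        (floored at the power law), else the pure power law."""
        frames = []
        for rep in range(1, self.cfg.replicates + 1):
            p = Path(self.cfg.data_dir) / f"hichip_{condition}_rep{rep}.bedpe"
            if p.exists():
                frames.append(smio.read_loops(p))
        if not frames:
            return abc_model.ContactModel(resolution=self.cfg.resolution)
        binned = loops_mod.bin_contacts(
            pd.concat(frames, ignore_index=True),
            self.cfg.resolution,
            self.cfg.min_loop_distance,
        )
        return abc_model.ContactModel(
            hic=binned.pairs, resolution=self.cfg.resolution
        )

    def abc(self) -> tuple[pd.DataFrame, dict]:
        peaks, genes, atac, elements = self._build_elements()
        k27 = self._counts("h3k27ac_counts.tsv")
        klf4_dbr_iv = None
        klf4_path = self.outdir / "klf4_dbr_results.tsv"
        if klf4_path.exists():
            klf4 = pd.read_csv(klf4_path, sep="\t")
            peak_by_id = {p.name: p for p in peaks}
            klf4_dbr_iv = [
                peak_by_id[i].interval
                for i in klf4[klf4["significant"]]["feature_id"]
                if i in peak_by_id
            ]
        deg_ids: Optional[set[str]] = None
        deg_path = self.outdir / "deg_results.tsv"
        if deg_path.exists():
            deg = pd.read_csv(deg_path, sep="\t")
            deg_ids = set(deg[deg["significant"]]["feature_id"])
        frames = []
        summaries = {}
        for cond in (self.cfg.condition_a, self.cfg.condition_b):
            quantified = abc_model.quantify_activity(elements, atac, k27, cond)
            table, summary = abc_model.predict_all(
                genes, quantified, threshold=self.cfg.abc_threshold,
                contact_model=self._contact_model(cond),
                klf4_dbr=klf4_dbr_iv, deg_ids=deg_ids,
            )
            table["condition"] = cond
            frames.append(table)
            summaries[cond] = summary
        predictions = pd.concat(frames, ignore_index=True)
        predictions.to_csv(self.outdir / "abc_predictions.tsv", sep="\t", index=False)
        _write_json(summaries, self.outdir / "abc_summary.json")
        n_pass = int((predictions["passes"] & ~predictions["is_promoter"]).sum())
        _log(f"abc: {n_pass} passing non-promoter predictions at "
             f"threshold {self.cfg.abc_threshold}")
        return predictions, summaries

    # -- loops ----------------------------------------------------------

    def _binned_by_sample(self) -> dict[str, loops_mod.BinnedContacts]:
        out = {}
        for cond in (self.cfg.condition_a, self.cfg.condition_b):
            for rep in range(1, self.cfg.replicates + 1):
                name = f"hichip_{cond}_rep{rep}.bedpe"
                pets = smio.read_loops(self.cfg.input_path(name))
                out[f"{cond}_rep{rep}"] = loops_mod.bin_contacts(
                    pets, self.cfg.resolution, self.cfg.min_loop_distance
                )
        return out

    def loops(self) -> tuple[pd.DataFrame, dict]:
        genes = self._genes()
        peaks = self._peaks()
        binned_by_sample = self._binned_by_sample()
        condition_of = {s: s.split("_")[0] for s in binned_by_sample}
        called_frames = []
        for cond in (self.cfg.condition_a, self.cfg.condition_b):
            pets = pd.concat(
                [
                    smio.read_loops(self.cfg.input_path(f"hichip_{cond}_rep{r}.bedpe"))
                    for r in range(1, self.cfg.replicates + 1)
                ],
                ignore_index=True,
            )
            binned = loops_mod.bin_contacts(
                pets, self.cfg.resolution, self.cfg.min_loop_distance
            )
            decay = loops_mod.fit_decay(binned)
            called, _ = loops_mod.call_loops(binned, decay, self.cfg.loop_q)
            called["condition"] = cond
            called_frames.append(called)
            _log(f"loops: {len(called)} significant pairs in {cond} at q < {self.cfg.loop_q}")
        union = (
            pd.concat(called_frames, ignore_index=True)
            .sort_values(["chrom", "bin1", "bin2", "q"], kind="mergesort")
            .drop_duplicates(["chrom", "bin1", "bin2"], keep="first")
            .reset_index(drop=True)
        )
        classified = loops_mod.classify_loops(
            union, [p.interval for p in peaks], genes,
            promoter_bp=self.cfg.promoter_bp, resolution=self.cfg.resolution,
        )
        final = loops_mod.differential_loops(
            classified, binned_by_sample, condition_of, alpha=self.cfg.alpha,
            condition_a=self.cfg.condition_a, condition_b=self.cfg.condition_b,
        )
        final.to_csv(self.outdir / "loops.tsv", sep="\t", index=False)
        class_counts = final["loop_class"].value_counts().to_dict()
        summary = {
            "n_loops": int(len(final)),
            "loop_classes": {k: int(v) for k, v in class_counts.items()},
            "n_ep": int((final["loop_class"] == "EP").sum()),
            "n_differential_ep": int(
                ((final["loop_class"] == "EP") & (final["differential"] != "stable")).sum()
            ),
            "n_gained": int((final["differential"] == "gained").sum()),
            "n_lost": int((final["differential"] == "lost").sum()),
        }
        _write_json(summary, self.outdir / "loop_summary.json")
        _log(f"loops: {summary['n_ep']} EP loops, "
             f"{summary['n_differential_ep']} differential")
        return final, summary

    # -- integration ----------------------------------------------------

    def integrate(self) -> dict:
        peaks = self._peaks()
        final = self._results("loops.tsv")
        deg = self._results("deg_results.tsv")
        klf4 = self._results("klf4_dbr_results.tsv")
        peak_by_id = {p.name: p for p in peaks}
        klf4_sig = klf4[klf4["significant"] & klf4["feature_id"].isin(peak_by_id)]
        klf4_dbr = pd.DataFrame(
            {
                "region_id": klf4_sig["feature_id"],
                "chrom": [peak_by_id[i].interval.chrom for i in klf4_sig["feature_id"]],
                "start": [peak_by_id[i].interval.start for i in klf4_sig["feature_id"]],
                "end": [peak_by_id[i].interval.end for i in klf4_sig["feature_id"]],
                "log2fc": klf4_sig["log2fc"],
            }
        )
        anchor_table, anchor_summary = loops_mod.klf4_at_anchors(
            final, klf4_dbr, deg, resolution=self.cfg.resolution
        )
        anchor_table.to_csv(self.outdir / "klf4_anchor_integration.tsv", sep="\t", index=False)

        predictions = self._results("abc_predictions.tsv")
        snps = smio.read_snps(self.cfg.input_path("snps.tsv"))
        snp_table, snp_summary = annotate.snp_overlap(snps, predictions)
        snp_table.to_csv(self.outdir / "snp_targets.tsv", sep="\t", index=False)

        out = {"klf4_anchors": anchor_summary, "snp": snp_summary}
        _write_json(out, self.outdir / "integration_summary.json")
        _log(
            f"integrate: {anchor_summary['n_anchors_with_differential_klf4']} KLF4 "
            f"anchors -> {anchor_summary['n_target_deg']} DEG; "
            f"{snp_summary['n_snps_in_elements']} SNPs -> "
            f"{snp_summary['n_target_genes']} genes"
        )
        return out

    # -- truth evaluation (synthetic runs) ------------------------------

    def evaluate_truth(self) -> dict:
        """Score ABC predictions and called loops against the planted truth
        tables (present only for simulated data)."""
        truth = synthetic.read_truth(self.cfg.data_dir)
        _, _, _, elements = self._build_elements()
        predictions = self._results("abc_predictions.tsv")
        abc_metrics, abc_recovered = abc_model.evaluate_links(
            predictions, truth.enhancer_gene_links, elements
        )
        final = self._results("loops.tsv")
        ep = final[final["loop_class"] == "EP"]
        ep_keys = set()
        for rec in ep.itertuples(index=False):
            for gid in str(rec.target_gene).split(","):
                if gid:
                    ep_keys.add(((int(rec.bin1), int(rec.bin2)), gid))
        loop_recovered = {
            (rid, gid)
            for rid, (gid, _) in truth.enhancer_gene_links.items()
            if rid in truth.loop_of_link
            and (truth.loop_of_link[rid], gid) in ep_keys
        }
        n_links = len(truth.enhancer_gene_links)
        both = abc_recovered & loop_recovered
        called_keys = set(zip(final["bin1"].astype(int), final["bin2"].astype(int)))
        loop_recall = (
            len(called_keys & truth.planted_loops) / len(truth.planted_loops)
            if truth.planted_loops
            else float("nan")
        )
        gained = final[final["differential"] == "gained"]
        gained_keys = set(zip(gained["bin1"].astype(int), gained["bin2"].astype(int)))
        lost = final[final["differential"] == "lost"]
        lost_keys = set(zip(lost["bin1"].astype(int), lost["bin2"].astype(int)))
        # directional recovery: loops of opening enhancers should be gained
        # under LSS, loops of closing (ST-active) enhancers lost
        up_keys = {
            truth.loop_of_link[r] for r in truth.up_regions() if r in truth.loop_of_link
        }
        down_keys = {
            truth.loop_of_link[r] for r in truth.down_regions() if r in truth.loop_of_link
        }
        n_directional = len(gained_keys & up_keys) + len(lost_keys & down_keys)
        out = {
            "abc": abc_metrics,
            "loop_recall": loop_recall,
            "n_planted_loops": len(truth.planted_loops),
            "frac_gained_among_lss_boosted": (
                len(gained_keys & up_keys) / len(up_keys) if up_keys else float("nan")
            ),
            "frac_planted_loops_directional": (
                n_directional / len(truth.planted_loops)
                if truth.planted_loops else float("nan")
            ),
            "frac_links_both_paths": len(both) / n_links if n_links else float("nan"),
            "n_links_abc": len(abc_recovered),
            "n_links_loops": len(loop_recovered),
        }
        _write_json(out, self.outdir / "truth_evaluation.json")
        _log(
            f"truth: ABC recall={abc_metrics['recall']:.2f} "
            f"precision={abc_metrics['precision']:.2f}, loop recall={loop_recall:.2f}, "
            f"both paths={out['frac_links_both_paths']:.2f}"
        )
        return out

    # -- everything -----------------------------------------------------

    def run_all(self, simulate_first: bool = False) -> dict:
        t0 = time.time()
        if simulate_first:
            self.simulate()
        dar = self.dar()
        deg = self.deg()
        self.dbr()
        motif_table = self.motifs()
        ann = self.annotate()
        _, abc_summaries = self.abc()
        _, loop_summary = self.loops()
        integration = self.integrate()
        truth_eval = None
        if (Path(self.cfg.data_dir) / "truth_links.tsv").exists():
            truth_eval = self.evaluate_truth()
        summary = {
            "n_dar_up": int((dar["significant"] & (dar["log2fc"] > 0)).sum()),
            "n_dar_down": int((dar["significant"] & (dar["log2fc"] < 0)).sum()),
            "n_deg_up": int((deg["significant"] & (deg["log2fc"] > 0)).sum()),
            "n_deg_down": int((deg["significant"] & (deg["log2fc"] < 0)).sum()),
            "annotation": ann,
            "abc": abc_summaries,
            "loops": loop_summary,
            "integration": integration,
            "truth_evaluation": truth_eval,
            "elapsed_s": round(time.time() - t0, 1),
        }
        _write_json(summary, self.outdir / "run_summary.json")
        self._write_manifest()
        self._write_report(summary, motif_table)
        _log(f"all: finished in {summary['elapsed_s']}s -> {self.outdir}")
        return summary

    def _write_manifest(self) -> None:
        data_dir = Path(self.cfg.data_dir)
        checksums = {
            p.name: _checksum(p)
            for p in sorted(data_dir.glob("*"))
            if p.is_file()
        }
        from . import __version__

        _write_json(
            {"config": asdict(self.cfg), "version": __version__, "inputs": checksums},
            self.outdir / "run_manifest.json",
        )

    def _write_report(self, summary: dict, motif_table: pd.DataFrame) -> None:
        lines = ["# Enhancer-landscape report", ""]
        lines += [
            "## Differential accessibility and expression",
            "",
            f"- DAR: {summary['n_dar_up']} up / {summary['n_dar_down']} down "
            f"(padj < {self.cfg.alpha})",
            f"- DEG: {summary['n_deg_up']} up / {summary['n_deg_down']} down",
            "",
            "## DAR annotation",
            "",
        ]
        for cat, n in summary["annotation"]["category_tally"].items():
            lines.append(f"- {cat}: {n}")
        hist = pd.read_csv(self.outdir / "dar_distance_histogram.tsv", sep="\t")
        lines += ["", "## Distance to nearest TSS", ""]
        for rec in hist.itertuples(index=False):
            lines.append(f"- [{rec.lo:g}, {rec.hi:g}): {rec.count}")
        lines += ["", "## Motif enrichment (opening DARs)", ""]
        lines.append("| motif | fg fraction | bg fraction | p |")
        lines.append("|---|---|---|---|")
        for rec in motif_table.itertuples(index=False):
            lines.append(
                f"| {rec.motif} | {rec.fg_fraction:.2f} | {rec.bg_fraction:.2f} "
                f"| {rec.binom_p:.3g} |"
            )
        ann = summary["annotation"]
        lines += [
            "",
            "## Accessibility-expression correlation",
            "",
            f"- Pearson r = {ann['dar_deg_r']:.3f} (p = {ann['dar_deg_p']:.3g}, "
            f"n = {ann['n_dar_deg_pairs']} DAR-DEG pairs)",
            "",
            "## KLF4/BRG1 co-occupancy of opening DARs",
            "",
        ]
        for k, v in ann["cooccupancy"]["fractions"].items():
            lines.append(f"- {k}: {v:.3f}")
        if ann["cooccupancy"].get("klf4_accessibility_r") is not None:
            lines.append(
                f"- KLF4 change vs accessibility change r = "
                f"{ann['cooccupancy']['klf4_accessibility_r']:.3f}"
            )
        lines += ["", "## ABC predictions", ""]
        for cond, s in summary["abc"].items():
            frag = f"- {cond}: {s['n_passing']} passing predictions"
            if "frac_deg_with_klf4_element" in s:
                frag += (
                    f"; {s['n_deg_with_klf4_element']}/{s['n_deg']} DEG with a "
                    f"passing KLF4-bound element"
                )
            lines.append(frag)
        ls = summary["loops"]
        lines += [
            "",
            "## HiChIP loops",
            "",
            f"- {ls['n_loops']} loops; classes: {ls['loop_classes']}",
            f"- {ls['n_ep']} EP loops, {ls['n_differential_ep']} differential "
            f"({ls['n_gained']} gained, {ls['n_lost']} lost)",
            "",
            "## KLF4 at enhancer anchors",
            "",
        ]
        ka = summary["integration"]["klf4_anchors"]
        lines.append(
            f"- differential KLF4 at {ka['n_anchors_with_differential_klf4']} enhancer "
            f"anchors regulating {ka['n_target_deg']} DEG"
        )
        sn = summary["integration"]["snp"]
        lines += [
            "",
            "## SNPs in predicted enhancers",
            "",
            f"- {sn['n_snps_in_elements']} SNPs inside passing elements, "
            f"predicted to target {sn['n_target_genes']} genes",
        ]
        if summary.get("truth_evaluation"):
            te = summary["truth_evaluation"]
            lines += [
                "",
                "## Planted-truth evaluation",
                "",
                f"- ABC recall {te['abc']['recall']:.2f} / precision "
                f"{te['abc']['precision']:.2f} at threshold {self.cfg.abc_threshold}",
                f"- loop recall {te['loop_recall']:.2f} at q < {self.cfg.loop_q}",
                f"- links found by both ABC and loop paths: "
                f"{te['frac_links_both_paths']:.2f}",
            ]
        (self.outdir / "report.md").write_text("\n".join(lines) + "\n")
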