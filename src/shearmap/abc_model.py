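"""Activity-by-Contact enhancer-to-gene prediction.

Candidate elements are built from accessibility peaks by the canonical
four-step recipe: resize each peak to a fixed width centred on its summit,
keep the top N by read count, drop blacklisted regions, merge overlaps.
Element activity is the geometric mean of accessibility (ATAC) and
H3K27ac signal, each normalized to reads-per-million over the candidate
set. Contact with a gene's promoter is either taken from user-supplied
contact records (floored at the power-law value) or modelled as
(distance + d0)^(-gamma), a standard surrogate for an average Hi-C
profile. The ABC score of element e for gene g is

    score(e, g) = A_e * C_eg / sum over elements e' in the gene's window

so scores for a gene sum to 1; predictions pass at ``score >= threshold``
(default 0.02). The gene's own promoter element is always present in the
denominator and receives the maximum contact in the window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import Gene, GenomicInterval, Peak, merge_intervals, overlaps, resize_to_summit
from .io import CountMatrix

DEFAULT_THRESHOLD = 0.02
DEFAULT_WINDOW_BP = 5_000_000
DEFAULT_GAMMA = 1.0
DEFAULT_D0 = 5_000


@dataclass(frozen=True)
class CandidateElement:
    element_id: str
    interval: GenomicInterval
    is_promoter: bool
    source_peaks: tuple[str, ...]
    atac_reads: float = 0.0
    h3k27ac_reads: float = 0.0
    activity: float = 0.0


def make_candidate_regions(
    peaks: Sequence[Peak],
    reads: Mapping[str, float],
    top_n: int = 150_000,
    blacklist: Sequence[GenomicInterval] = (),
    width: int = 250,
) -> list[CandidateElement]:
    """Build candidate enhancer elements from peaks.

    Pipeline order: resize each peak to ``width`` bp centred on its summit;
    rank by ``reads`` (keyed by peak name) and keep the ``top_n`` with the
    most reads (ties broken by (chrom, start)); drop any region overlapping
    the blacklist by >= 1 bp; merge overlapping regions. Merged elements
    remember their source peak names so counts can be aggregated.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    missing = [p.name for p in peaks if p.name not in reads]
    if missing:
        raise ValueError(f"peaks without read counts: {missing[:5]}")
    resized = [(resize_to_summit(p, width), p.name) for p in peaks]
    ranked = sorted(
        resized, key=lambda t: (-reads[t[1]], t[0].chrom, t[0].start)
    )[:top_n]
    kept = [
        (iv, name)
        for iv, name in ranked
        if not any(overlaps(iv, b) for b in blacklist)
    ]
    merged = merge_intervals([iv for iv, _ in kept])
    elements: list[CandidateElement] = []
    for i, iv in enumerate(merged):
        sources = tuple(
            sorted(name for siv, name in kept if overlaps(siv, iv))
        )
        elements.append(
            CandidateElement(f"element_{i+1:04d}", iv, False, sources)
        )
    return elements


def promoter_elements(genes: Sequence[Gene], half_width: int = 250) -> list[CandidateElement]:
    """One promoter element per gene: TSS +/- half_width, always included in
    the ABC denominator. Its counts are looked up under 'prom_<gene_id>'."""
    out = []
    for g in genes:
        start = max(0, g.tss - half_width)
        iv = GenomicInterval(g.interval.chrom, start, g.tss + half_width)
        out.append(
            CandidateElement(f"prom_{g.gene_id}", iv, True, (f"prom_{g.gene_id}",))
        )
    return out


def _condition_sums(m: CountMatrix, condition: str) -> dict[str, float]:
    cols = m.samples_of(condition)
    if not cols:
        raise ValueError(f"no samples for condition {condition!r}")
    sums = np.asarray(m.counts, dtype=float)[:, cols].sum(axis=1)
    return dict(zip(m.feature_ids, sums))


def quantify_activity(
    elements: Sequence[CandidateElement],
    atac: CountMatrix,
    h3k27ac: CountMatrix,
    condition: str,
) -> list[CandidateElement]:
    """Attach activity = sqrt(atac_rpm * h3k27ac_rpm) to each element.

    Reads are replicate-summed within ``condition`` and aggregated over
    each element's source peaks, then each assay is normalized to
    reads-per-million over the candidate set. Zero in either assay gives
    activity 0.
    """
    atac_sum = _condition_sums(atac, condition)
    k27_sum = _condition_sums(h3k27ac, condition)

    def gather(sums: dict[str, float], e: CandidateElement) -> float:
        total = 0.0
        for src in e.source_peaks:
            if src not in sums:
                raise ValueError(f"no counts for element source {src!r} (element {e.element_id})")
            total += sums[src]
        return total

    atac_reads = np.array([gather(atac_sum, e) for e in elements])
    k27_reads = np.array([gather(k27_sum, e) for e in elements])
    atac_rpm = atac_reads / max(atac_reads.sum(), 1.0) * 1e6
    k27_rpm = k27_reads / max(k27_reads.sum(), 1.0) * 1e6
    activity = np.sqrt(atac_rpm * k27_rpm)
    return [
        replace(e, atac_reads=float(a), h3k27ac_reads=float(k), activity=float(act))
        for e, a, k, act in zip(elements, atac_reads, k27_reads, activity)
    ]


class ContactModel:
    """Power-law contact with an optional observed-contact override.

    Contact between positions p1 and p2 on the same chromosome is
    (|p1 - p2| + d0)^(-gamma). When binned contact records are supplied
    (columns chrom, bin1, bin2, count at ``resolution``), the observed
    normalized count is used instead, floored at the power-law value so
    unobserved bins never zero out a prediction.
    """

    def __init__(
        self,
        gamma: float = DEFAULT_GAMMA,
        d0: float = DEFAULT_D0,
        hic: Optional[pd.DataFrame] = None,
        resolution: int = 1000,
    ):
        self.gamma = gamma
        self.d0 = d0
        self.resolution = resolution
        self._observed: dict[tuple[str, int, int], float] = {}
        if hic is not None and len(hic):
            # scale observed counts onto the power-law axis: background
            # pairs satisfy count ~ N * powerlaw(d), so
            # sum(powerlaw) / sum(count) estimates 1/N (a minority of
            # genuinely looped pairs barely moves the sums)
            d = np.abs(hic["bin2"].to_numpy() - hic["bin1"].to_numpy()) * resolution
            counts = hic["count"].to_numpy(dtype=float)
            norm = float(((d + d0) ** (-gamma)).sum() / max(counts.sum(), 1.0))
            for rec in hic.itertuples(index=False):
                b1, b2 = sorted((int(rec.bin1), int(rec.bin2)))
                self._observed[(str(rec.chrom), b1, b2)] = float(rec.count) * norm

    def powerlaw(self, distance: float) -> float:
        return float((abs(distance) + self.d0) ** (-self.gamma))

    def contact(self, chrom_a: str, pos_a: int, chrom_b: str, pos_b: int) -> float:
        if chrom_a != chrom_b:
            return 0.0
        base = self.powerlaw(pos_b - pos_a)
        if self._observed:
            b1, b2 = sorted((pos_a // self.resolution, pos_b // self.resolution))
            obs = self._observed.get((chrom_a, b1, b2))
            if obs is not None:
                return max(obs, base)
        return base


def contact(
    element: GenomicInterval,
    gene: Gene,
    hic: Optional[pd.DataFrame] = None,
    gamma: float = DEFAULT_GAMMA,
    d0: float = DEFAULT_D0,
    resolution: int = 1000,
) -> float:
    """Contact between an element midpoint and a gene TSS (0 across
    chromosomes)."""
    model = ContactModel(gamma=gamma, d0=d0, hic=hic, resolution=resolution)
    return model.contact(element.chrom, element.midpoint, gene.interval.chrom, gene.tss)


def abc_scores(
    gene: Gene,
    elements: Sequence[CandidateElement],
    threshold: float = DEFAULT_THRESHOLD,
    window_bp: float = DEFAULT_WINDOW_BP,
    contact_model: Optional[ContactModel] = None,
) -> pd.DataFrame:
    """ABC scores of all candidate elements in the gene's window.

    The window is TSS +/- window_bp/2 on the gene's chromosome. The gene's
    own promoter element receives the maximum contact over the window
    (self-contact convention). Scores are normalized to sum to 1 (all 0
    when every A*C product is 0). ``passes`` is score >= threshold.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    model = contact_model or ContactModel()
    tss = gene.tss
    half = window_bp / 2
    in_window = [
        e
        for e in elements
        if e.interval.chrom == gene.interval.chrom
        and abs(e.interval.midpoint - tss) <= half
    ]
    if not in_window:
        return pd.DataFrame(
            columns=[
                "element_id", "chrom", "start", "end", "gene_id", "distance",
                "activity", "contact", "score", "passes", "is_promoter",
            ]
        )
    contacts = np.array(
        [
            model.contact(e.interval.chrom, e.interval.midpoint, gene.interval.chrom, tss)
            for e in in_window
        ]
    )
    own = f"prom_{gene.gene_id}"
    max_contact = contacts.max() if len(contacts) else 0.0
    for i, e in enumerate(in_window):
        if e.element_id == own:
            contacts[i] = max_contact
    products = np.array([e.activity for e in in_window]) * contacts
    denom = products.sum()
    scores = products / denom if denom > 0 else np.zeros_like(products)
    return pd.DataFrame(
        {
            "element_id": [e.element_id for e in in_window],
            "chrom": [e.interval.chrom for e in in_window],
            "start": [e.interval.start for e in in_window],
            "end": [e.interval.end for e in in_window],
            "gene_id": gene.gene_id,
            "distance": [e.interval.midpoint - tss for e in in_window],
            "activity": [e.activity for e in in_window],
            "contact": contacts,
            "score": scores,
            "passes": scores >= threshold,
            "is_promoter": [e.is_promoter for e in in_window],
        }
    )


def predict_all(
    genes: Sequence[Gene],
    elements: Sequence[CandidateElement],
    threshold: float = DEFAULT_THRESHOLD,
    window_bp: float = DEFAULT_WINDOW_BP,
    contact_model: Optional[ContactModel] = None,
    klf4_dbr: Optional[Sequence[GenomicInterval]] = None,
    deg_ids: Optional[set[str]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Concatenated ABC predictions for every gene, plus a summary.

    With ``klf4_dbr`` given, each prediction is flagged when its element
    overlaps a differentially KLF4-bound region by >= 1 bp; with
    ``deg_ids`` also given, the summary reports the fraction of those DEG
    with at least one passing KLF4-bound non-promoter element.
    """
    model = contact_model or ContactModel()
    frames = [
        abc_scores(g, elements, threshold, window_bp, model) for g in genes
    ]
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if klf4_dbr is not None and len(table):
        from .annotate import _IntervalIndex

        idx = _IntervalIndex(list(klf4_dbr))
        table["overlaps_klf4_dbr"] = [
            idx.overlaps(r.chrom, r.start, r.end) for r in table.itertuples(index=False)
        ]
    summary: dict = {
        "n_genes": len(genes),
        "n_passing": int(table["passes"].sum()) if len(table) else 0,
    }
    if deg_ids is not None and "overlaps_klf4_dbr" in getattr(table, "columns", []):
        passing = table[table["passes"] & ~table["is_promoter"] & table["overlaps_klf4_dbr"]]
        hit_genes = set(passing["gene_id"]) & deg_ids
        summary["n_deg"] = len(deg_ids)
        summary["n_deg_with_klf4_element"] = len(hit_genes)
        summary["frac_deg_with_klf4_element"] = (
            len(hit_genes) / len(deg_ids) if deg_ids else 0.0
        )
    return table, summary


def evaluate_links(
    predictions: pd.DataFrame, true_links: Mapping[str, tuple[str, float]],
    elements: Sequence[CandidateElement],
) -> tuple[dict[str, float], set[tuple[str, str]]]:
    """Recall/precision of passing non-promoter predictions against planted
    enhancer-gene links.

    A planted link (region, gene) counts as recovered when a passing
    element containing that region targets that gene; a passing
    (element, gene) pair is a true positive when the element contains a
    planted region linked to that gene.
    """
    region_of_element: dict[str, set[str]] = {
        e.element_id: set(e.source_peaks) for e in elements
    }
    passing = predictions[predictions["passes"] & ~predictions["is_promoter"]]
    passing_pairs = set(zip(passing["element_id"], passing["gene_id"]))
    true_pairs = {(rid, gid) for rid, (gid, _) in true_links.items()}
    recovered = set()
    tp_pairs = set()
    for eid, gid in passing_pairs:
        for rid in region_of_element.get(eid, ()):
            if (rid, gid) in true_pairs:
                recovered.add((rid, gid))
                tp_pairs.add((eid, gid))
    recall = len(recovered) / len(true_pairs) if true_pairs else float("nan")
    precision = len(tp_pairs) / len(passing_pairs) if passing_pairs else float("nan")
    metrics = {
        "n_true_links": len(true_pairs),
        "n_passing_pairs": len(passing_pairs),
        "n_recovered": len(recovered),
        "recall": recall,
        "precision": precision,
    }
    return metrics, recovered
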