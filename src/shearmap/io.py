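"""Readers and writers for the plain-text formats the pipeline touches.

BED3/BED6, ENCODE narrowPeak (10 columns), BEDPE (anchor pairs with an
optional count), a 6-column gene TSV (or GTF-lite ``gene`` lines), TSV count
matrices (first column feature_id, header row of sample ids), JASPAR-like
PWM text, TSV SNP and contact tables, FASTA. All tab-separated; lines
beginning with '#' are ignored. Every writer/reader pair round-trips
losslessly for valid data.

Coordinates on disk follow each format's own convention (BED half-open,
GTF 1-based inclusive); everything is converted to 0-based half-open here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Gene, GenomicInterval, Peak


# ---------------------------------------------------------------------------
# count matrix


@dataclass
class CountMatrix:
    """Features x samples matrix of non-negative integer counts.

    ``condition_of`` maps every sample id to its condition label
    (e.g. "LSS" or "ST").
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature_ids")
        missing = [s for s in self.sample_ids if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[int]:
        """Column indices of the samples belonging to ``condition``."""
        return [
            j for j, s in enumerate(self.sample_ids) if self.condition_of[s] == condition
        ]

    def subset(self, feature_ids: Sequence[str]) -> "CountMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in feature_ids]
        return CountMatrix(
            list(feature_ids), list(self.sample_ids), self.counts[rows], dict(self.condition_of)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SNPRecord:
    rsid: str
    chrom: str
    pos: int  # 0-based

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"SNP {self.rsid}: pos must be >= 0")


# ---------------------------------------------------------------------------
# helpers


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _parse_int(token: str, path, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: bad {what} {token!r}") from exc


def warn_on_chrom_mismatch(chroms_a: Iterable[str], chroms_b: Iterable[str],
                           label_a: str = "first file", label_b: str = "second file") -> set[str]:
    """Warn when two inputs share no chromosome names; return the shared set.

    Chromosome names are compared as exact strings (no 'chr' normalization):
    silent renaming would hide genuine data errors.
    """
    a, b = set(chroms_a), set(chroms_b)
    shared = a & b
    if a and b and not shared:
        warnings.warn(
            f"no chromosome names shared between {label_a} ({sorted(a)[:3]}...) and "
            f"{label_b} ({sorted(b)[:3]}...); records on unshared chromosomes are dropped"
        )
    return shared


# ---------------------------------------------------------------------------
# regions (BED / narrowPeak)


def read_regions(path: str | Path, format: str = "narrowPeak") -> list[Peak]:
    """Read peaks from BED3/BED6 or ENCODE narrowPeak.

    BED: summit defaults to the interval midpoint, signal to BED score
    (column 5) when present. narrowPeak: summit = column 10 (-1 means
    midpoint), signal = signalValue (column 7).
    """
    if format not in {"bed", "narrowPeak"}:
        raise ValueError(f"unknown region format {format!r}")
    peaks: list[Peak] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if format == "narrowPeak" and len(fields) != 10:
            raise ValueError(
                f"{path}:{lineno}: narrowPeak requires 10 tab-separated columns, "
                f"got {len(fields)}"
            )
        if format == "bed" and len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED requires >= 3 columns")
        chrom = fields[0]
        start = _parse_int(fields[1], path, lineno, "start")
        end = _parse_int(fields[2], path, lineno, "end")
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
        name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
        strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
        if format == "narrowPeak":
            signal = float(fields[6])
            summit = _parse_int(fields[9], path, lineno, "summit offset")
            if summit == -1:
                summit = (end - start) // 2
        else:
            signal = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            summit = (end - start) // 2
        peaks.append(
            Peak(GenomicInterval(chrom, start, end, strand), summit, signal, name)
        )
    return peaks


def write_regions(peaks: Sequence[Peak], path: str | Path, format: str = "narrowPeak") -> None:
    if format not in {"bed", "narrowPeak"}:
        raise ValueError(f"unknown region format {format!r}")
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    with open(path, "w") as fh:
        for p in rows:
            iv = p.interval
            name = p.name or "."
            if format == "narrowPeak":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}"
                    f"\t{p.signal:g}\t-1\t-1\t{p.summit_offset}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{p.signal:g}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# BEDPE anchor pairs


def read_loops(path: str | Path) -> pd.DataFrame:
    """Read a BEDPE file of anchor pairs.

    Returns a DataFrame with columns chrom1, start1, end1, chrom2, start2,
    end2, name, count. The BEDPE score column carries the tag count
    (defaults to 1 when absent or '.').
    """
    rows = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 6:
            raise ValueError(f"{path}:{lineno}: BEDPE requires >= 6 columns")
        try:
            count = int(f[7]) if len(f) > 7 and f[7] != "." else 1
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad count {f[7]!r}") from exc
        rows.append(
            (
                f[0],
                _parse_int(f[1], path, lineno, "start1"),
                _parse_int(f[2], path, lineno, "end1"),
                f[3],
                _parse_int(f[4], path, lineno, "start2"),
                _parse_int(f[5], path, lineno, "end2"),
                f[6] if len(f) > 6 else ".",
                count,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "count"],
    )
    bad = (df["start1"] >= df["end1"]) | (df["start2"] >= df["end2"])
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} BEDPE records with start >= end")
    return df


def write_loops(loops: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    df = loops.copy()
    if "name" not in df.columns:
        df["name"] = "."
    if "count" not in df.columns:
        df["count"] = 1
    df = df.sort_values(cols, kind="mergesort")
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            fh.write(
                f"{r.chrom1}\t{r.start1}\t{r.end1}\t{r.chrom2}\t{r.start2}\t{r.end2}"
                f"\t{r.name}\t{int(r.count)}\n"
            )


# ---------------------------------------------------------------------------
# genes


_GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]


def read_genes(path: str | Path) -> list[Gene]:
    """Read genes from a 6-column TSV or from GTF-lite ``gene`` lines.

    The TSV carries 0-based half-open coordinates; GTF (detected by a
    9-column layout or a .gtf suffix) is 1-based inclusive and converted.
    """
    path = Path(path)
    genes: list[Gene] = []
    is_gtf: Optional[bool] = True if path.suffix.lower() == ".gtf" else None
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if is_gtf is None:
            is_gtf = len(f) == 9
        if is_gtf:
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: GTF requires 9 columns")
            if f[2] != "gene":
                continue
            attrs = {}
            for item in f[8].strip().strip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip().strip('"')
            gene_id = attrs.get("gene_id", "")
            symbol = attrs.get("gene_name", gene_id)
            start = _parse_int(f[3], path, lineno, "start") - 1  # 1-based -> 0-based
            end = _parse_int(f[4], path, lineno, "end")  # inclusive -> half-open
            strand = f[6]
        else:
            if f == _GENE_COLUMNS:  # header row
                continue
            if len(f) != 6:
                raise ValueError(f"{path}:{lineno}: gene TSV requires 6 columns")
            gene_id, symbol, chrom = f[0], f[1], f[2]
            start = _parse_int(f[3], path, lineno, "start")
            end = _parse_int(f[4], path, lineno, "end")
            strand = f[5]
            genes.append(Gene(gene_id, symbol, GenomicInterval(chrom, start, end), strand))
            continue
        if not gene_id:
            raise ValueError(f"{path}:{lineno}: GTF gene line without gene_id")
        genes.append(Gene(gene_id, symbol, GenomicInterval(f[0], start, end), strand))
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate gene_ids")
    return genes


def write_genes(genes: Sequence[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            fh.write(f"{g.gene_id}\t{g.symbol}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# count matrices


def read_counts(
    path: str | Path, condition_of: Optional[Mapping[str, str]] = None
) -> CountMatrix:
    """Read a TSV count matrix: first column feature_id, header of sample ids.

    When ``condition_of`` is not given, each sample's condition is inferred
    as the prefix before the first underscore (e.g. ``LSS_rep1`` -> ``LSS``).
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate feature_ids")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    if not np.allclose(df.values, np.round(df.values)):
        raise ValueError(f"{path}: non-integer counts")
    samples = [str(c) for c in df.columns]
    if condition_of is None:
        condition_of = {s: s.split("_")[0] for s in samples}
    return CountMatrix(
        [str(i) for i in df.index],
        samples,
        df.values.astype(np.int64),
        dict(condition_of),
    )


def write_counts(m: CountMatrix, path: str | Path) -> None:
    m.to_frame().rename_axis("feature_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SNPs, contacts


def read_snps(path: str | Path) -> list[SNPRecord]:
    """Read a SNP TSV with columns rsid, chrom, pos (0-based)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"rsid": str, "chrom": str})
    for col in ("rsid", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [SNPRecord(r.rsid, r.chrom, int(r.pos)) for r in df.itertuples(index=False)]


def write_snps(snps: Sequence[SNPRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(s.rsid, s.chrom, s.pos) for s in snps], columns=["rsid", "chrom", "pos"]
    ).to_csv(path, sep="\t", index=False)


def read_contacts(path: str | Path) -> pd.DataFrame:
    """Read a contact TSV with columns chrom, bin1, bin2, count."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    for col in ("chrom", "bin1", "bin2", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative contact counts")
    return df


def write_contacts(contacts: pd.DataFrame, path: str | Path) -> None:
    contacts[["chrom", "bin1", "bin2", "count"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PWM


def read_pwm(path: str | Path):
    """Read a JASPAR-like PWM: optional '>name' header, then 4 rows A/C/G/T.

    Each row is the base letter followed by L tab/space-separated
    probabilities (square brackets tolerated).
    """
    from .motifs import PWM  # local import to avoid a cycle

    name = Path(path).stem
    rows: dict[str, list[float]] = {}
    for lineno, line in _data_lines(path):
        if line.startswith(">"):
            name = line[1:].strip().split()[0]
            continue
        tokens = line.replace("[", " ").replace("]", " ").split()
        if not tokens:
            continue
        base = tokens[0].upper()
        if base not in "ACGT":
            raise ValueError(f"{path}:{lineno}: expected a row starting with A/C/G/T")
        rows[base] = [float(t) for t in tokens[1:]]
    if set(rows) != set("ACGT"):
        raise ValueError(f"{path}: PWM needs exactly one row for each of A, C, G, T")
    probs = np.array([rows[b] for b in "ACGT"])
    return PWM(name=name, probs=probs)


def write_pwm(pwm, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for i, base in enumerate("ACGT"):
            fh.write(base + "\t" + "\t".join(f"{v:.10f}" for v in pwm.probs[i]) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
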