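"""PWM scanning and binomial motif enrichment.

A motif is a position probability matrix (rows A, C, G, T). Windows are
scored as log-odds against a uniform 0.25 background with a small
pseudocount, both strands are scanned, and a window is a hit when its score
reaches a fixed fraction of the maximum achievable score. Enrichment of a
motif in a foreground region set (e.g. regions gaining accessibility) over
a background set (accessible but not differential regions) is assessed by
an upper-tail exact binomial test, the statistic behind classic
known-motif enrichment tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import binomial_tail

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

PSEUDOCOUNT = 1e-3


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with rows A, C, G, T (columns sum to 1)."""

    name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError("PWM probs must be a 4 x L matrix")
        if probs.shape[1] < 4:
            raise ValueError("PWM length must be >= 4")
        if np.any(probs < 0):
            raise ValueError("PWM probabilities must be non-negative")
        colsums = probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ValueError("each PWM column must sum to 1 within 1e-6")

    def __len__(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """4 x L matrix of log2((p + pseudocount) / 0.25)."""
        return np.log2((self.probs + PSEUDOCOUNT) / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=0))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to indices 0..3; anything else (N) becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _scan_one_strand(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Scores for every window of len(lo.T) over encoded sequence codes;
    windows containing N score -inf."""
    L = lo.shape[1]
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    # sliding windows of base indices
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    scores = lo[safe, np.arange(L)].sum(axis=1)
    scores[~valid] = -np.inf
    return scores


def pwm_scan(
    seq: str, pwm: PWM, threshold_frac: float = 0.8
) -> list[tuple[int, str, float]]:
    """Scan both strands of ``seq`` for PWM hits.

    Returns (position, strand, score) triples, position being the 0-based
    start of the window on the forward strand. A window is a hit when its
    log-odds score >= threshold_frac * maximum achievable score; windows
    containing N never hit. Sequences shorter than the motif yield [].
    """
    if not (0 < threshold_frac <= 1):
        raise ValueError("threshold_frac must lie in (0, 1]")
    L = len(pwm)
    if len(seq) < L:
        return []
    threshold = threshold_frac * pwm.max_score
    lo = pwm.log_odds
    codes = _encode(seq)
    hits: list[tuple[int, str, float]] = []
    fwd = _scan_one_strand(codes, lo)
    for pos in np.nonzero(fwd >= threshold)[0]:
        hits.append((int(pos), "+", float(fwd[pos])))
    rc_codes = _encode(reverse_complement(seq))
    rev = _scan_one_strand(rc_codes, lo)
    n = len(seq)
    for pos in np.nonzero(rev >= threshold)[0]:
        # window [pos, pos+L) on the reverse complement maps to
        # [n-pos-L, n-pos) on the forward strand
        hits.append((int(n - pos - L), "-", float(rev[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def has_motif(seq: str, pwm: PWM, threshold_frac: float = 0.8) -> bool:
    return bool(pwm_scan(seq, pwm, threshold_frac))


def motif_enrichment(
    fg_regions: Sequence[str],
    bg_regions: Sequence[str],
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
    threshold_frac: float = 0.8,
) -> pd.DataFrame:
    """Binomial enrichment of each PWM in foreground vs background regions.

    ``fg_regions`` and ``bg_regions`` are region ids keyed into
    ``sequences``. A region "has" a motif when pwm_scan reports >= 1 hit.
    The null hit probability p0 is the background fraction (clamped away
    from 0 and 1) and the p-value is the exact upper-tail binomial
    P(X >= fg_with | n = fg_total, p0). Results are sorted by p-value.
    """
    if not fg_regions:
        raise ValueError("empty foreground region set")
    if not bg_regions:
        raise ValueError("empty background region set")
    missing = [r for r in list(fg_regions) + list(bg_regions) if r not in sequences]
    if missing:
        raise ValueError(f"regions without sequences: {missing[:5]}")
    rows = []
    for pwm in pwms:
        fg_with = sum(has_motif(sequences[r], pwm, threshold_frac) for r in fg_regions)
        bg_with = sum(has_motif(sequences[r], pwm, threshold_frac) for r in bg_regions)
        fg_total, bg_total = len(fg_regions), len(bg_regions)
        p0 = min(max(bg_with / bg_total, 1e-12), 1 - 1e-12)
        binom_p = binomial_tail(fg_with, fg_total, p0)
        fg_fraction = fg_with / fg_total
        rows.append(
            {
                "motif": pwm.name,
                "fg_with": fg_with,
                "fg_total": fg_total,
                "bg_with": bg_with,
                "bg_total": bg_total,
                "fg_fraction": fg_fraction,
                "bg_fraction": bg_with / bg_total,
                "binom_p": binom_p,
                "fold": fg_fraction / p0,
            }
        )
    out = pd.DataFrame(rows).sort_values("binom_p", kind="mergesort")
    return out.reset_index(drop=True)


def shuffle_pwm_columns(pwm: PWM, rng: np.random.Generator, tag: str = "shuffled") -> PWM:
    """Decoy motif: the same columns in a random order (information content
    preserved, consensus destroyed). Permutations that reproduce the
    original consensus are rejected."""
    for _ in range(1000):
        perm = rng.permutation(len(pwm))
        decoy = PWM(name=f"{pwm.name}_{tag}", probs=pwm.probs[:, perm])
        if decoy.consensus != pwm.consensus:
            return decoy
    raise ValueError(f"could not shuffle {pwm.name}: consensus invariant to permutation")
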