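"""Ping-pong 5'-overlap profile, per-overlap Z-scores, and 1U/10A bias.

The ping-pong amplification cycle leaves two fingerprints in mapped piRNAs:
an excess of sense/antisense read pairs whose 5' ends overlap by exactly
10 nt, and nucleotide biases (U at read position 1 of primary piRNAs, A at
position 10 of secondary ones).  The overlap score at distance d is the sum
over opposite-strand pairs of the product of their weights; the Z-score of
d = 10 against the d = 1..30 background is the standard ping-pong statistic.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import normalize, revcomp
from .align import AlignedRead

BASES = ("A", "C", "G", "T")


def overlap_scores(alignments: Iterable[AlignedRead], max_d: int = 30) -> np.ndarray:
    """Overlap score S_d for d = 1..max_d (returned as array index d-1).

    For a plus-strand alignment with 5' position p and a minus-strand
    alignment with 5' position q >= p on the same chromosome, the pair
    overlaps by d = q - p + 1 5'-anchored bases and contributes
    weight_plus * weight_minus to S_d.
    """
    minus: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    plus: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    for a in alignments:
        side = plus if a.strand == "+" else minus
        side[a.chrom][a.five_prime] += a.weight
    S = np.zeros(max_d)
    for chrom, ppos in plus.items():
        mpos = minus.get(chrom)
        if not mpos:
            continue
        for p, wp in ppos.items():
            for d in range(1, max_d + 1):
                wm = mpos.get(p + d - 1)
                if wm:
                    S[d - 1] += wp * wm
    return S


def zscores(S: np.ndarray) -> np.ndarray:
    """Z-score of each overlap length's share of the total overlap score.

    r_d = S_d / sum(S); z_d = (r_d - mean(r)) / sd(r) with the population
    standard deviation over d.  All-zero S or zero sd yield all-zero z.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 1 or len(S) < 2:
        raise ValueError("need scores for at least two overlap lengths")
    total = S.sum()
    if total == 0:
        return np.zeros_like(S)
    r = S / total
    sd = r.std()  # population sd
    if sd == 0:
        return np.zeros_like(S)
    return (r - r.mean()) / sd


def pingpong_profile(
    alignments: Iterable[AlignedRead], max_d: int = 30
) -> pd.DataFrame:
    """Tidy profile: overlap length d, score S_d, ratio r_d, z_d."""
    S = overlap_scores(alignments, max_d=max_d)
    total = S.sum()
    r = S / total if total > 0 else np.zeros_like(S)
    z = zscores(S)
    return pd.DataFrame(
        {"d": np.arange(1, max_d + 1), "S": S, "ratio": r, "z": z}
    )


def shuffled_null_zscores(
    alignments: Sequence[AlignedRead],
    rng: np.random.Generator,
    max_d: int = 30,
) -> np.ndarray:
    """One replicate of the shuffled null for the overlap Z-score.

    Strands are reassigned at random (preserving the observed plus
    fraction) and 5' positions are redrawn uniformly over each
    chromosome's observed 5' span, which destroys any pairing structure
    while keeping read numbers, weights, and overall density.  Returns the
    z vector of the shuffled data.
    """
    per_chrom: dict[str, list[float]] = defaultdict(list)
    spans: dict[str, tuple[int, int]] = {}
    n_plus = 0
    n_total = 0
    for a in alignments:
        per_chrom[a.chrom].append(a.weight)
        fp = a.five_prime
        lo, hi = spans.get(a.chrom, (fp, fp))
        spans[a.chrom] = (min(lo, fp), max(hi, fp))
        n_total += 1
        n_plus += a.strand == "+"
    if n_total == 0:
        raise ValueError("empty alignment set")
    p_plus = n_plus / n_total
    S = np.zeros(max_d)
    for chrom, weights in per_chrom.items():
        lo, hi = spans[chrom]
        pos = rng.integers(lo, hi + 1, size=len(weights))
        plus_mask = rng.random(len(weights)) < p_plus
        minus: dict[int, float] = defaultdict(float)
        for p, w, is_plus in zip(pos, weights, plus_mask):
            if not is_plus:
                minus[int(p)] += w
        for p, w, is_plus in zip(pos, weights, plus_mask):
            if is_plus:
                for d in range(1, max_d + 1):
                    wm = minus.get(int(p) + d - 1)
                    if wm:
                        S[d - 1] += w * wm
    return zscores(S)


@dataclass(frozen=True)
class BaseBiasProfile:
    """Weighted base frequencies over the first 10 read positions.

    ``frequencies`` is a (positions x 4) frame with columns A,C,G,T whose
    rows each sum to 1.  ``u1`` and ``a10`` are the canonical summaries:
    fraction U(=T) at position 1 and fraction A at position 10.
    ``skipped`` counts alignments whose 5' window ran off the chromosome.
    """

    frequencies: pd.DataFrame
    u1: float
    a10: float
    skipped: int


def base_bias(
    alignments: Iterable[AlignedRead],
    genome: dict[str, str],
    n_positions: int = 10,
) -> BaseBiasProfile:
    """Weighted base composition of the 5'-most ``n_positions`` read bases.

    Bases are read in read orientation: for minus-strand alignments the
    genomic window ending at the 5' end is reverse-complemented.  Raises
    ``ValueError`` on an empty alignment set.
    """
    counts = np.zeros((n_positions, 4))
    skipped = 0
    n_seen = 0
    norm_genome = {c: normalize(s) for c, s in genome.items()}
    base_idx = {b: i for i, b in enumerate(BASES)}
    for a in alignments:
        n_seen += 1
        seq = norm_genome[a.chrom]
        if a.strand == "+":
            lo, hi = a.start, a.start + n_positions
            if lo < 0 or hi > len(seq):
                skipped += 1
                continue
            window = seq[lo:hi]
        else:
            hi = a.end
            lo = hi - n_positions
            if lo < 0 or hi > len(seq):
                skipped += 1
                continue
            window = revcomp(seq[lo:hi])
        for i, b in enumerate(window):
            j = base_idx.get(b)
            if j is not None:
                counts[i, j] += a.weight
    if n_seen == 0:
        raise ValueError("empty alignment set")
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(row_sums > 0, counts / row_sums, 0.0)
    frame = pd.DataFrame(
        freqs, index=pd.RangeIndex(1, n_positions + 1, name="position"),
        columns=list(BASES),
    )
    u1 = float(frame.loc[1, "T"]) if n_positions >= 1 else float("nan")
    a10 = float(frame.loc[10, "A"]) if n_positions >= 10 else float("nan")
    return BaseBiasProfile(frequencies=frame, u1=u1, a10=a10, skipped=skipped)


def length_histogram(alignments: Iterable[AlignedRead]) -> pd.Series:
    """Summed alignment weight per read length."""
    acc: dict[int, float] = defaultdict(float)
    for a in alignments:
        acc[a.length] += a.weight
    s = pd.Series(dict(sorted(acc.items())), dtype=float)
    s.index.name = "length"
    return s


def normalize_counts(histogram: pd.Series, total_mapped: float) -> pd.Series:
    """Scale a length histogram by 10^7 / total mapped piRNA count."""
    if total_mapped <= 0:
        raise ValueError("total mapped count must be positive")
    return histogram * (1e7 / total_mapped)
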