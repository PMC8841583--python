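"""Mapping piRNA candidates to a genome with a seed-anchored mismatch rule,
best-stratum selection, and multimapper weight reallocation.

The mapping contract: the 5'-most 18 nt of a read (the seed) must match the
genome exactly; up to two mismatches are tolerated, but only strictly after
the seed and not in the last two read positions.  For each read the
minimum-mismatch stratum of alignments is retained, and multimapper counts
are then split across retained loci in proportion to the local density of
uniquely-mapping reads.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from ._seq import KmerIndex, encode, normalize, revcomp
from .filters import SmallRNARead

SEED_LENGTH = 18
TERMINAL_PROTECT = 2
MAX_MISMATCHES = 2


@dataclass(frozen=True)
class AlignedRead:
    """One genomic occurrence of a mapped small-RNA read.

    ``start`` is the 0-based position of the leftmost aligned base;
    ``mismatch_positions`` are 1-based read coordinates counted from the
    read's 5' end (so for minus-strand alignments position 1 is the
    rightmost genomic base).  ``weight`` is the reallocated share of the
    read's copy count carried by this locus.
    """

    read_id: str
    chrom: str
    start: int
    strand: str
    length: int
    mismatch_positions: tuple[int, ...] = ()
    count: int = 1
    weight: float = 0.0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if any(p < 1 or p > self.length for p in self.mismatch_positions):
            raise ValueError("mismatch positions outside the read")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """Genomic position of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


def valid_mismatch_pattern(
    length: int,
    mismatch_positions: Sequence[int],
    seed_length: int = SEED_LENGTH,
    terminal_protect: int = TERMINAL_PROTECT,
    max_mismatches: int = MAX_MISMATCHES,
) -> bool:
    """True iff no mismatch in the seed, none in the protected 3' terminal
    positions, and at most ``max_mismatches`` total."""
    if len(mismatch_positions) > max_mismatches:
        return False
    for p in mismatch_positions:
        if p <= seed_length or p > length - terminal_protect:
            return False
    return True


class ReadTooShortError(ValueError):
    """Read shorter than seed + protected tail + one variable position."""


def _mismatch_read_positions(
    genome_codes: np.ndarray, pattern: np.ndarray, start: int, strand: str
) -> tuple[int, ...]:
    """1-based read-coordinate mismatch positions of `pattern` (genome-strand
    oriented) placed at `start`."""
    L = len(pattern)
    window = genome_codes[start : start + L]
    diff = np.nonzero((window != pattern) | (window >= 4) | (pattern >= 4))[0]
    if strand == "+":
        pos = diff + 1
    else:
        pos = L - diff  # pattern index i is read position L - i
    return tuple(sorted(int(p) for p in pos))


class GenomeMapper:
    """Reusable mapper over one genome (dict of chromosome -> sequence)."""

    def __init__(
        self,
        genome: dict[str, str],
        seed_length: int = SEED_LENGTH,
        terminal_protect: int = TERMINAL_PROTECT,
        max_mismatches: int = MAX_MISMATCHES,
    ):
        self.genome = {c: normalize(s) for c, s in genome.items()}
        self.seed_length = seed_length
        self.terminal_protect = terminal_protect
        self.max_mismatches = max_mismatches
        self._index = KmerIndex(self.genome, seed_length)
        self._codes = {c: encode(s) for c, s in self.genome.items()}
        self._chroms = list(self.genome)

    def enumerate_alignments(self, read: SmallRNARead) -> list[AlignedRead]:
        """Every genomic occurrence of the read satisfying the mismatch rule,
        on both strands, sorted by (chrom, start, strand)."""
        L = len(read)
        if L < self.seed_length + self.terminal_protect + 1:
            raise ReadTooShortError(
                f"read {read.id} ({L} nt) shorter than "
                f"{self.seed_length + self.terminal_protect + 1} nt minimum"
            )
        seq = normalize(read.sequence)
        hits: list[AlignedRead] = []
        # plus strand: seed = read[:k] anchored at alignment start
        for cid, off in zip(*self._index.lookup(seq[:self.seed_length])):
            chrom = self._chroms[cid]
            start = int(off)
            hits.extend(self._check(read, seq, chrom, start, "+"))
        # minus strand: the read's reverse complement lies on the forward
        # genome; the seed occupies the *last* k bases of that pattern
        rc = revcomp(seq)
        for cid, off in zip(*self._index.lookup(rc[L - self.seed_length :])):
            chrom = self._chroms[cid]
            start = int(off) - (L - self.seed_length)
            hits.extend(self._check(read, rc, chrom, start, "-"))
        hits.sort(key=lambda a: (a.chrom, a.start, a.strand))
        return hits

    def _check(
        self, read: SmallRNARead, pattern: str, chrom: str, start: int, strand: str
    ) -> list[AlignedRead]:
        codes = self._codes[chrom]
        L = len(pattern)
        if start < 0 or start + L > len(codes):
            return []
        mm = _mismatch_read_positions(codes, encode(pattern), start, strand)
        if not valid_mismatch_pattern(
            L, mm, self.seed_length, self.terminal_protect, self.max_mismatches
        ):
            return []
        return [
            AlignedRead(
                read_id=read.id, chrom=chrom, start=start, strand=strand,
                length=L, mismatch_positions=mm, count=read.count,
            )
        ]


def enumerate_alignments(
    read: SmallRNARead, genome: dict[str, str], **kwargs
) -> list[AlignedRead]:
    """One-shot convenience wrapper around :class:`GenomeMapper`."""
    return GenomeMapper(genome, **kwargs).enumerate_alignments(read)


def select_min_mismatch(alignments: Sequence[AlignedRead]) -> list[AlignedRead]:
    """Retain the minimum-mismatch stratum of one read's alignments."""
    if not alignments:
        return []
    ids = {a.read_id for a in alignments}
    if len(ids) != 1:
        raise ValueError("alignments must belong to a single read")
    best = min(len(a.mismatch_positions) for a in alignments)
    kept = [a for a in alignments if len(a.mismatch_positions) == best]
    kept.sort(key=lambda a: (a.chrom, a.start, a.strand))
    return kept


def reallocate_weights(
    alignments: Iterable[AlignedRead], window: int = 10_000
) -> list[AlignedRead]:
    """Assign per-locus weights so each read's weights sum to its count.

    Uniquely-mapping reads carry their full count.  A multimapper's count is
    split across its loci proportionally to U(locus): the summed count of
    uniquely-mapped reads whose 5' ends fall within +-window/2 of the locus
    5' end on the same chromosome.  If U = 0 everywhere, the split is
    uniform.
    """
    by_read: dict[str, list[AlignedRead]] = defaultdict(list)
    for a in alignments:
        by_read[a.read_id].append(a)

    # index of unique-mapper 5' ends per chromosome
    uniq_pos: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for alns in by_read.values():
        if len(alns) == 1:
            a = alns[0]
            uniq_pos[a.chrom].append((a.five_prime, a.count))
    uniq_sorted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pairs in uniq_pos.items():
        pairs.sort()
        pos = np.array([p for p, _ in pairs], dtype=np.int64)
        cum = np.concatenate(([0], np.cumsum([c for _, c in pairs])))
        uniq_sorted[chrom] = (pos, cum)

    half = window / 2.0

    def unique_density(chrom: str, fp: int) -> float:
        if chrom not in uniq_sorted:
            return 0.0
        pos, cum = uniq_sorted[chrom]
        lo = np.searchsorted(pos, fp - half, side="left")
        hi = np.searchsorted(pos, fp + half, side="right")
        return float(cum[hi] - cum[lo])

    out: list[AlignedRead] = []
    for alns in by_read.values():
        if len(alns) == 1:
            out.append(replace(alns[0], weight=float(alns[0].count)))
            continue
        dens = np.array([unique_density(a.chrom, a.five_prime) for a in alns])
        total = dens.sum()
        if total == 0:
            shares = np.full(len(alns), 1.0 / len(alns))
        else:
            shares = dens / total
        for a, s in zip(alns, shares):
            out.append(replace(a, weight=float(a.count) * float(s)))
    out.sort(key=lambda a: (a.chrom, a.start, a.strand, a.read_id))
    return out


def map_reads(
    reads: Iterable[SmallRNARead],
    genome: dict[str, str],
    window: int = 10_000,
    mapper: GenomeMapper | None = None,
) -> list[AlignedRead]:
    """Full mapping pipeline: enumerate, best-stratum select, reallocate.

    Reads with no valid alignment are dropped silently; reads shorter than
    the mapper minimum raise :class:`ReadTooShortError`.
    """
    if mapper is None:
        mapper = GenomeMapper(genome)
    selected: list[AlignedRead] = []
    for read in reads:
        alns = mapper.enumerate_alignments(read)
        selected.extend(select_min_mismatch(alns))
    return reallocate_weights(selected, window=window)
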