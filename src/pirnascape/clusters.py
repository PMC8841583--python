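"""piRNA cluster calling by two complementary detectors, plus set comparison.

The density detector finds broad regions rich in distinct piRNA 5' loci and
applies the two operative filters: at least 1 locus/kb and at least 10 loci
per cluster.  The assembly-style detector chains nearby read footprints into
fragments and merges fragments into clusters, suited to narrow loci.  The
two detections are unioned; cluster sets from two samples (e.g. ovary and
testis) are compared by interval overlap.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .align import AlignedRead


@dataclass(frozen=True)
class PiRNACluster:
    """A genomic interval emitting many piRNAs (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_loci: int
    read_weight: float
    sample: str = "unlabeled"
    method: str = "density"
    strandedness: str = "unknown"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("cluster end must exceed start")
        if self.n_loci < 1:
            raise ValueError("cluster must contain at least one locus")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def density(self) -> float:
        """Distinct piRNA 5' loci per kb."""
        return self.n_loci / (self.length / 1000.0)

    def overlap(self, other: "PiRNACluster") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _loci_by_chrom(
    alignments: Sequence[AlignedRead],
) -> dict[str, np.ndarray]:
    acc: dict[str, set[int]] = defaultdict(set)
    for a in alignments:
        acc[a.chrom].add(a.five_prime)
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in acc.items()}


def _cluster_stats(
    alignments: Sequence[AlignedRead], chrom: str, start: int, end: int
) -> tuple[int, float, str]:
    """(n_loci, weight, strandedness) of alignments with 5' end in [start, end)."""
    loci = set()
    weight = 0.0
    w_plus = 0.0
    for a in alignments:
        if a.chrom == chrom and start <= a.five_prime < end:
            loci.add(a.five_prime)
            weight += a.weight
            if a.strand == "+":
                w_plus += a.weight
    if weight > 0:
        frac = w_plus / weight
        if frac >= 0.8:
            strandedness = "plus"
        elif frac <= 0.2:
            strandedness = "minus"
        else:
            strandedness = "bidirectional"
    else:
        strandedness = "unknown"
    return len(loci), weight, strandedness


def detect_density(
    alignments: Sequence[AlignedRead],
    window: int = 5_000,
    min_density: float = 1.0,
    min_loci: int = 10,
    sample: str = "unlabeled",
) -> list[PiRNACluster]:
    """Density-based cluster calls.

    Distinct 5' loci separated by at most ``window`` are chained into
    candidate regions, trimmed to the outermost loci; a candidate survives
    iff its locus density is >= ``min_density`` loci/kb AND it holds at
    least ``min_loci`` distinct loci.
    """
    clusters = []
    for chrom, loci in _loci_by_chrom(alignments).items():
        if len(loci) == 0:
            continue
        breaks = np.nonzero(np.diff(loci) > window)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(loci) - 1]))
        for si, ei in zip(starts, ends):
            first, last = int(loci[si]), int(loci[ei])
            start, end = first, last + 1
            n_loci = int(ei - si + 1)
            length = end - start
            if n_loci < min_loci:
                continue
            if n_loci / (length / 1000.0) < min_density:
                continue
            _, weight, strandedness = _cluster_stats(alignments, chrom, start, end)
            clusters.append(
                PiRNACluster(
                    chrom=chrom, start=start, end=end, n_loci=n_loci,
                    read_weight=weight, sample=sample, method="density",
                    strandedness=strandedness,
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.start))
    return clusters


def detect_assembly(
    alignments: Sequence[AlignedRead],
    min_frag: int = 50,
    gap: int = 50,
    min_len: int = 500,
    merge_gap: int = 250,
    min_weight: float = 50.0,
    sample: str = "unlabeled",
) -> list[PiRNACluster]:
    """Two-stage assembly-style cluster calls.

    Stage 1 chains alignment footprints separated by <= ``gap`` bases into
    fragments and drops fragments shorter than ``min_frag``.  Stage 2 merges
    fragments separated by <= ``merge_gap``, keeping merged intervals with
    length >= ``min_len`` and summed alignment weight >= ``min_weight``.
    """
    by_chrom: dict[str, list[AlignedRead]] = defaultdict(list)
    for a in alignments:
        by_chrom[a.chrom].append(a)
    clusters = []
    for chrom, alns in by_chrom.items():
        ivals = sorted((a.start, a.end) for a in alns)
        # stage 1: chain into fragments
        frags: list[list[int]] = []
        for s, e in ivals:
            if frags and s - frags[-1][1] <= gap:
                frags[-1][1] = max(frags[-1][1], e)
            else:
                frags.append([s, e])
        frags = [f for f in frags if f[1] - f[0] >= min_frag]
        # stage 2: merge fragments
        merged: list[list[int]] = []
        for s, e in frags:
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s < min_len:
                continue
            n_loci, weight, strandedness = _cluster_stats(alignments, chrom, s, e)
            if weight < min_weight or n_loci == 0:
                continue
            clusters.append(
                PiRNACluster(
                    chrom=chrom, start=s, end=e, n_loci=n_loci,
                    read_weight=weight, sample=sample, method="assembly",
                    strandedness=strandedness,
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.start))
    return clusters


def union_clusters(
    density_set: Sequence[PiRNACluster],
    assembly_set: Sequence[PiRNACluster],
    alignments: Sequence[AlignedRead] | None = None,
) -> list[PiRNACluster]:
    """Union of the two detections.

    Overlapping clusters merge into their union interval (method
    ``merged``); non-overlapping ones pass through.  When ``alignments``
    are supplied, locus counts and weights of merged intervals are
    recomputed; otherwise they are summed approximately.
    """
    todo = sorted(
        list(density_set) + list(assembly_set), key=lambda c: (c.chrom, c.start)
    )
    out: list[PiRNACluster] = []
    for c in todo:
        if out and out[-1].chrom == c.chrom and c.start < out[-1].end:
            prev = out[-1]
            merged_from_both = prev.method != c.method or prev.method == "merged"
            method = "merged" if merged_from_both else prev.method
            new = replace(
                prev,
                end=max(prev.end, c.end),
                n_loci=max(prev.n_loci, c.n_loci),
                read_weight=max(prev.read_weight, c.read_weight),
                method=method,
            )
            out[-1] = new
        else:
            out.append(c)
    if alignments is not None:
        refreshed = []
        for c in out:
            n_loci, weight, strandedness = _cluster_stats(
                alignments, c.chrom, c.start, c.end
            )
            refreshed.append(
                replace(
                    c, n_loci=max(n_loci, 1), read_weight=weight,
                    strandedness=strandedness,
                )
            )
        out = refreshed
    return out


def common_clusters(
    set_a: Sequence[PiRNACluster],
    set_b: Sequence[PiRNACluster],
    min_frac: float = 0.5,
    reciprocal: bool = False,
    labels: tuple[str, str] = ("ovary", "testis"),
) -> tuple[list[tuple[PiRNACluster, PiRNACluster]], list[PiRNACluster], list[PiRNACluster]]:
    """Pair clusters shared between two samples.

    A pair is *common* iff their overlap exceeds ``min_frac`` of the shorter
    cluster (strictly greater), or of both clusters in ``reciprocal`` mode.
    Returns (common pairs, A-specific, B-specific); clusters in pairs are
    relabeled sample="common".
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for j, b in enumerate(set_b):
        trees[b.chrom][b.start:b.end] = j
    pairs = []
    matched_a: set[int] = set()
    matched_b: set[int] = set()
    for i, a in enumerate(set_a):
        for iv in sorted(trees[a.chrom][a.start:a.end]):
            j = iv.data
            b = set_b[j]
            ov = a.overlap(b)
            if reciprocal:
                ok = ov > min_frac * a.length and ov > min_frac * b.length
            else:
                ok = ov > min_frac * min(a.length, b.length)
            if ok:
                pairs.append(
                    (replace(a, sample="common"), replace(b, sample="common"))
                )
                matched_a.add(i)
                matched_b.add(j)
    only_a = [
        replace(a, sample=labels[0])
        for i, a in enumerate(set_a) if i not in matched_a
    ]
    only_b = [
        replace(b, sample=labels[1])
        for j, b in enumerate(set_b) if j not in matched_b
    ]
    return pairs, only_a, only_b


@dataclass(frozen=True)
class ChromMap:
    """Homologous-chromosome pairing with an optional affine transform.

    A position x on the source chromosome maps to scale * x + offset on
    ``target``.
    """

    target: str
    scale: float = 1.0
    offset: float = 0.0

    def map_interval(self, start: int, end: int) -> tuple[int, int]:
        a = self.scale * start + self.offset
        b = self.scale * end + self.offset
        lo, hi = (a, b) if a <= b else (b, a)
        return int(round(lo)), int(round(hi))


def location_conservation(
    set_a: Sequence[PiRNACluster],
    set_b: Sequence[PiRNACluster],
    chrom_map: Mapping[str, ChromMap],
) -> float:
    """Fraction of A-clusters with any B-cluster overlapping their mapped
    location.  Clusters on unmapped chromosomes count as non-conserved."""
    if not set_a:
        raise ValueError("empty query cluster set")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for b in set_b:
        trees[b.chrom][b.start:b.end] = True
    hit = 0
    for a in set_a:
        cmap = chrom_map.get(a.chrom)
        if cmap is None:
            continue
        lo, hi = cmap.map_interval(a.start, a.end)
        if hi > lo and trees[cmap.target].overlaps(lo, hi):
            hit += 1
    return hit / len(set_a)


def match_to_truth(
    called: Sequence[PiRNACluster],
    truth_intervals: Sequence[tuple[str, int, int]],
    min_frac: float = 0.5,
) -> tuple[float, float]:
    """(precision, recall) of cluster calls against planted intervals.

    A call matches a truth interval when their reciprocal overlap exceeds
    ``min_frac`` of each interval.
    """
    def reciprocal(c: PiRNACluster, t: tuple[str, int, int]) -> bool:
        chrom, s, e = t
        if c.chrom != chrom:
            return False
        ov = max(0, min(c.end, e) - max(c.start, s))
        return ov > min_frac * c.length and ov > min_frac * (e - s)

    matched_calls = sum(1 for c in called if any(reciprocal(c, t) for t in truth_intervals))
    matched_truth = sum(1 for t in truth_intervals if any(reciprocal(c, t) for c in called))
    precision = matched_calls / len(called) if called else 0.0
    recall = matched_truth / len(truth_intervals) if truth_intervals else 1.0
    return precision, recall
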