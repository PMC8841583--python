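"""Per-base genome classification into eight categories and fraction tables.

Every genome base receives exactly one label out of: DNA transposon,
retrotransposon, satellite, simple repeat, unknown repeat, exon, intron,
other.  Where annotations overlap, repeats win over genes and exons win
over introns; overlaps *between* repeat annotations are resolved first by
giving contested bases to the family with the lower diversity score
(younger, better-defined family).
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignedRead
from .landscape import copy_divergence

CATEGORIES = (
    "dna_transposon",
    "retrotransposon",
    "satellite",
    "simple_repeat",
    "unknown_repeat",
    "exon",
    "intron",
    "other",
)
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}

#: repeat_class vocabulary -> category
REPEAT_CLASS_TO_CATEGORY = {
    "DNA": "dna_transposon",
    "LINE": "retrotransposon",
    "SINE": "retrotransposon",
    "LTR": "retrotransposon",
    "satellite": "satellite",
    "simple": "simple_repeat",
    "unknown": "unknown_repeat",
}


@dataclass(frozen=True)
class RepeatAnnotation:
    """A repeat interval with class/superfamily/family and optional
    divergence (substitutions/site) to the family consensus."""

    chrom: str
    start: int
    end: int
    repeat_class: str
    superfamily: str = ""
    family: str = ""
    divergence: float | None = None
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("invalid repeat interval")
        if self.repeat_class not in REPEAT_CLASS_TO_CATEGORY:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")

    @property
    def category(self) -> str:
        return REPEAT_CLASS_TO_CATEGORY[self.repeat_class]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon intervals (introns are the gaps between)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        for s, e in self.exons:
            if s < self.start or e > self.end or e <= s:
                raise ValueError(f"exon outside gene {self.gene_id}")


def family_diversity(
    copies: Sequence[str], consensus: str | None = None
) -> tuple[float, bool]:
    """Mean pairwise K2P distance among a family's copies.

    Copies must share the consensus coordinate frame (equal lengths, no
    indels).  Returns (diversity, reliable); a single-copy family returns
    (0.0, False) — flagged as uninformative.
    """
    if len(copies) == 0:
        raise ValueError("no copies")
    if len(copies) == 1:
        return 0.0, False
    dists = [
        copy_divergence(a, b).K for a, b in combinations(copies, 2)
    ]
    return float(np.mean(dists)), True


def resolve_repeat_overlaps(
    annotations: Sequence[RepeatAnnotation],
    diversities: Mapping[str, float],
) -> list[RepeatAnnotation]:
    """Make repeat annotations disjoint, contested bases going to the
    annotation whose family diversity is lower.

    Ties break by earlier start, then lexicographic family name.  Output
    intervals are disjoint and sorted; annotations fully shadowed by
    lower-diversity ones disappear.
    """
    for ann in annotations:
        if ann.family not in diversities:
            raise KeyError(f"no diversity score for family {ann.family!r}")
    order = sorted(
        annotations,
        key=lambda a: (diversities[a.family], a.start, a.family),
    )
    covered: dict[str, list[tuple[int, int]]] = defaultdict(list)
    out: list[RepeatAnnotation] = []
    for ann in order:
        pieces = _subtract(ann.start, ann.end, sorted(covered[ann.chrom]))
        for s, e in pieces:
            out.append(
                RepeatAnnotation(
                    chrom=ann.chrom, start=s, end=e,
                    repeat_class=ann.repeat_class, superfamily=ann.superfamily,
                    family=ann.family, divergence=ann.divergence,
                    strand=ann.strand,
                )
            )
        covered[ann.chrom].append((ann.start, ann.end))
    out.sort(key=lambda a: (a.chrom, a.start))
    return out


def _subtract(
    start: int, end: int, blocked: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """[start, end) minus a sorted list of blocked intervals."""
    pieces = []
    cur = start
    for s, e in blocked:
        if e <= cur or s >= end:
            continue
        if s > cur:
            pieces.append((cur, min(s, end)))
        cur = max(cur, e)
        if cur >= end:
            break
    if cur < end:
        pieces.append((cur, end))
    return pieces


class CategoryMap:
    """Per-base category labels for a genome (one uint8 array per chrom)."""

    def __init__(self, labels: dict[str, np.ndarray]):
        self.labels = labels

    @property
    def genome_length(self) -> int:
        return sum(len(v) for v in self.labels.values())

    def category_at(self, chrom: str, pos: int) -> str:
        return CATEGORIES[self.labels[chrom][pos]]

    def fractions(self) -> pd.Series:
        """Fraction of genome bases per category (sums to 1)."""
        counts = np.zeros(len(CATEGORIES), dtype=np.int64)
        for arr in self.labels.values():
            counts += np.bincount(arr, minlength=len(CATEGORIES))
        s = pd.Series(counts / counts.sum(), index=list(CATEGORIES))
        s.index.name = "category"
        return s

    def rle(self) -> pd.DataFrame:
        """Run-length export: chrom, start, end, category."""
        rows = []
        for chrom, arr in self.labels.items():
            if len(arr) == 0:
                continue
            change = np.nonzero(np.diff(arr))[0]
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [len(arr)]))
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s), int(e), CATEGORIES[arr[s]]))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "category"])


def classify_genome(
    repeats: Sequence[RepeatAnnotation],
    genes: Sequence[GeneModel],
    genome_lengths: Mapping[str, int],
) -> CategoryMap:
    """Label every base with priority repeat > exon > intron > other.

    ``repeats`` must already be disjoint (see
    :func:`resolve_repeat_overlaps`); exons must lie within their gene
    (validated by :class:`GeneModel`).
    """
    labels = {
        c: np.full(n, _CAT_INDEX["other"], dtype=np.uint8)
        for c, n in genome_lengths.items()
    }
    # paint lowest priority first so later paints win: intron, exon, repeat
    for g in genes:
        labels[g.chrom][g.start : g.end] = _CAT_INDEX["intron"]
    for g in genes:
        for s, e in g.exons:
            labels[g.chrom][s:e] = _CAT_INDEX["exon"]
    seen: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for r in repeats:
        for s0, e0 in seen[r.chrom]:
            if min(e0, r.end) > max(s0, r.start):
                raise ValueError("repeat annotations must be disjoint")
        seen[r.chrom].append((r.start, r.end))
        labels[r.chrom][r.start : r.end] = _CAT_INDEX[r.category]
    return CategoryMap(labels)


def fraction_table(
    category_map: CategoryMap,
    alignments: Iterable[AlignedRead] | None = None,
    intervals: Sequence[tuple[str, int, int]] | None = None,
) -> pd.Series:
    """Per-category fractions of piRNA weight or of interval bases.

    With ``alignments``: fraction of total alignment weight whose 5' base
    falls in each category.  With ``intervals`` (e.g. a cluster set):
    fraction of the covered bases per category.  With neither: genome-wide
    base fractions.  Fractions sum to 1.
    """
    if alignments is not None and intervals is not None:
        raise ValueError("pass alignments or intervals, not both")
    if alignments is not None:
        acc = np.zeros(len(CATEGORIES))
        for a in alignments:
            cat = category_map.labels[a.chrom][a.five_prime]
            acc[cat] += a.weight
        total = acc.sum()
        if total == 0:
            raise ValueError("no alignment weight")
        s = pd.Series(acc / total, index=list(CATEGORIES))
        s.index.name = "category"
        return s
    if intervals is not None:
        acc = np.zeros(len(CATEGORIES), dtype=np.int64)
        for chrom, start, end in intervals:
            arr = category_map.labels[chrom][start:end]
            acc += np.bincount(arr, minlength=len(CATEGORIES))
        if acc.sum() == 0:
            raise ValueError("empty interval set")
        s = pd.Series(acc / acc.sum(), index=list(CATEGORIES))
        s.index.name = "category"
        return s
    return category_map.fractions()
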