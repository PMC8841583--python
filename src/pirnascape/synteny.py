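"""Synteny of piRNA clusters across (sub)genomes via flanking-exon anchors.

piRNA clusters themselves evolve fast, so conservation of the *locus* is
judged from the neighborhood: the ten nearest exons on each side of a
cluster are searched against the other genome with a seeded, X-drop-extended
local aligner; a cluster is called syntenic when enough of its anchor exons
land together, in order, in one region of the target.  Whether the cluster
body itself still has a homolog there is reported separately, which is what
distinguishes "conserved cluster" from "cluster turnover at a conserved
locus".
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import KmerIndex, encode, normalize, revcomp
from .clusters import PiRNACluster
from .composition import GeneModel


@dataclass(frozen=True)
class Scoring:
    """Local-alignment scoring; defaults fixed for reproducibility."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2


@dataclass(frozen=True)
class ExonAnchor:
    chrom: str
    start: int
    end: int
    sequence: str


@dataclass(frozen=True)
class SyntenyAnchor:
    """Up to ten flanking exons on each side of a cluster."""

    cluster: PiRNACluster
    upstream: tuple[ExonAnchor, ...]
    downstream: tuple[ExonAnchor, ...]

    @property
    def exons(self) -> tuple[ExonAnchor, ...]:
        """All anchor exons in genomic order."""
        return tuple(sorted(self.upstream + self.downstream,
                            key=lambda e: e.start))


@dataclass(frozen=True)
class Hit:
    """A local alignment of a query against the target genome."""

    chrom: str
    target_start: int
    target_end: int
    strand: str
    query_start: int
    query_end: int
    score: float
    identity: float

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass(frozen=True)
class HitGroup:
    exon_indices: tuple[int, ...]
    chrom: str
    target_start: int
    target_end: int
    total_score: float
    collinear: bool


@dataclass(frozen=True)
class SyntenyCall:
    cluster: PiRNACluster
    n_homologous_exons: int
    total_bit_score: float
    syntenic: bool
    cluster_body_conserved: bool
    target_cluster_present: bool
    target_region: tuple[str, int, int] | None
    diagnostic: str = ""


def flanking_exons(
    cluster: PiRNACluster,
    genes: Sequence[GeneModel],
    genome: dict[str, str],
    n: int = 10,
    min_cluster_length: int = 1000,
) -> SyntenyAnchor:
    """The ``n`` nearest exons up- and downstream of a cluster.

    Only clusters longer than ``min_cluster_length`` qualify for synteny
    analysis; shorter ones raise ``ValueError``.  Fewer exons are returned
    near chromosome ends.
    """
    if cluster.length <= min_cluster_length:
        raise ValueError(
            f"cluster of {cluster.length} bp not longer than "
            f"{min_cluster_length} bp; excluded from synteny analysis"
        )
    seq = genome[cluster.chrom]
    exons = sorted(
        {
            (s, e)
            for g in genes
            if g.chrom == cluster.chrom
            for s, e in g.exons
        }
    )
    up = [(s, e) for s, e in exons if e <= cluster.start]
    down = [(s, e) for s, e in exons if s >= cluster.end]
    up = up[-n:]
    down = down[:n]
    mk = lambda iv: ExonAnchor(cluster.chrom, iv[0], iv[1], seq[iv[0]:iv[1]])
    return SyntenyAnchor(
        cluster=cluster,
        upstream=tuple(mk(iv) for iv in up),
        downstream=tuple(mk(iv) for iv in down),
    )


class SimilaritySearch:
    """Seeded, ungapped X-drop local search against one target genome.

    Exact ``seed_k``-mers anchor candidate diagonals; each is extended in
    both directions under the scoring scheme until the running score drops
    ``xdrop`` below its maximum, then trimmed to the best-scoring span.
    Gap penalties are part of the scoring contract but the default
    extension is ungapped, which is exact for substitution-only divergence.
    """

    def __init__(
        self,
        target_genome: dict[str, str],
        seed_k: int = 10,
        scoring: Scoring = Scoring(),
        xdrop: int = 20,
        min_score: int = 15,
    ):
        self.genome = {c: normalize(s) for c, s in target_genome.items()}
        self.codes = {c: encode(s) for c, s in self.genome.items()}
        self.chroms = list(self.genome)
        self.index = KmerIndex(self.genome, seed_k)
        self.seed_k = seed_k
        self.scoring = scoring
        self.xdrop = xdrop
        self.min_score = min_score

    def search(self, query: str, min_rel_size: float = 0.10) -> list[Hit]:
        """Local hits of ``query`` on both strands, best score first.

        Hits whose aligned query span is below ``min_rel_size`` of the
        query length are discarded.
        """
        query = normalize(query)
        Lq = len(query)
        hits: list[Hit] = []
        for strand in "+-":
            pattern = query if strand == "+" else revcomp(query)
            hits.extend(self._search_pattern(pattern, strand, Lq))
        min_span = min_rel_size * Lq
        hits = [h for h in hits if h.query_span >= min_span]
        hits.sort(key=lambda h: (-h.score, h.chrom, h.target_start))
        return self._dedup(hits)

    @staticmethod
    def _dedup(hits: list[Hit]) -> list[Hit]:
        """Drop hits mostly contained in a better hit on the same strand."""
        kept: list[Hit] = []
        for h in hits:
            redundant = False
            for k in kept:
                if k.chrom != h.chrom or k.strand != h.strand:
                    continue
                ov = min(k.target_end, h.target_end) - max(
                    k.target_start, h.target_start
                )
                span = h.target_end - h.target_start
                if span > 0 and ov / span > 0.5:
                    redundant = True
                    break
            if not redundant:
                kept.append(h)
        return kept

    def _search_pattern(self, pattern: str, strand: str, Lq: int) -> list[Hit]:
        k = self.seed_k
        pcodes = encode(pattern)
        Lp = len(pattern)
        covered: dict[tuple[int, int], list[tuple[int, int]]] = {}
        hits = []
        for qpos in range(0, Lp - k + 1):
            ids, offs = self.index.lookup(pattern[qpos : qpos + k])
            for cid, off in zip(ids.tolist(), offs.tolist()):
                diag = off - qpos
                spans = covered.setdefault((cid, diag), [])
                if any(s <= qpos < e for s, e in spans):
                    continue
                res = self._extend(pcodes, self.codes[self.chroms[cid]],
                                   qpos, off)
                if res is None:
                    continue
                qs, qe, score, ident = res
                spans.append((qs, qe))
                if score < self.min_score:
                    continue
                ts, te = qs + diag, qe + diag
                if strand == "+":
                    oqs, oqe = qs, qe
                else:
                    oqs, oqe = Lq - qe, Lq - qs
                hits.append(
                    Hit(
                        chrom=self.chroms[cid], target_start=ts, target_end=te,
                        strand=strand, query_start=oqs, query_end=oqe,
                        score=score, identity=ident,
                    )
                )
        return hits

    def _extend(
        self, pcodes: np.ndarray, tcodes: np.ndarray, qpos: int, tpos: int
    ) -> tuple[int, int, float, float] | None:
        """Ungapped X-drop extension around a seed on one diagonal.

        Returns (query_start, query_end, score, identity) of the trimmed
        maximal-scoring span.
        """
        m, mm, xdrop = self.scoring.match, self.scoring.mismatch, self.xdrop
        diag = tpos - qpos
        lo = max(0, -diag)
        hi = min(len(pcodes), len(tcodes) - diag)
        if hi <= lo:
            return None
        eq = (pcodes[lo:hi] == tcodes[lo + diag : hi + diag]) & (pcodes[lo:hi] < 4)
        step = np.where(eq, m, mm).astype(float)
        anchor = qpos - lo
        # right extension with X-drop
        right = self._xdrop_walk(step[anchor:], xdrop)
        # left extension over reversed prefix (anchor base included on right)
        left = self._xdrop_walk(step[:anchor][::-1], xdrop)
        qs = qpos - left
        qe = qpos + right
        if qe <= qs:
            return None
        span = eq[qs - lo : qe - lo]
        score = float(step[qs - lo : qe - lo].sum())
        if score <= 0:
            return None
        identity = float(span.mean())
        return qs, qe, score, identity

    @staticmethod
    def _xdrop_walk(step: np.ndarray, xdrop: float) -> int:
        """Length of the maximal-scoring prefix before an X-drop stop."""
        if len(step) == 0:
            return 0
        cum = np.cumsum(step)
        run_max = np.maximum.accumulate(cum)
        stopped = np.nonzero(run_max - cum > xdrop)[0]
        limit = stopped[0] if len(stopped) else len(step)
        if limit == 0:
            return 0
        return int(np.argmax(cum[:limit])) + 1


def group_hits(
    exon_hits: Sequence[Sequence[Hit]],
    max_span: int = 1_000_000,
) -> list[HitGroup]:
    """Group exons whose best hits co-locate in the target.

    Each exon contributes its best-scoring hit; hits on one chromosome
    within ``max_span`` of each other form a group.  A group is collinear
    when target order follows exon order (forward or reversed).
    """
    best: list[tuple[int, Hit]] = []
    for i, hits in enumerate(exon_hits):
        if hits:
            best.append((i, max(hits, key=lambda h: h.score)))
    by_chrom: dict[str, list[tuple[int, Hit]]] = {}
    for i, h in best:
        by_chrom.setdefault(h.chrom, []).append((i, h))
    groups = []
    for chrom, members in by_chrom.items():
        members.sort(key=lambda ih: ih[1].target_start)
        chains: list[list[tuple[int, Hit]]] = []
        for i, h in members:
            if chains and h.target_start - chains[-1][-1][1].target_end <= max_span:
                chains[-1].append((i, h))
            else:
                chains.append([(i, h)])
        for chain in chains:
            idx = [i for i, _ in chain]
            by_exon_order = sorted(chain, key=lambda ih: ih[0])
            tpos = [h.target_start for _, h in by_exon_order]
            collinear = tpos == sorted(tpos) or tpos == sorted(tpos, reverse=True)
            groups.append(
                HitGroup(
                    exon_indices=tuple(sorted(idx)),
                    chrom=chrom,
                    target_start=min(h.target_start for _, h in chain),
                    target_end=max(h.target_end for _, h in chain),
                    total_score=sum(h.score for _, h in chain),
                    collinear=collinear,
                )
            )
    groups.sort(key=lambda g: (-len(g.exon_indices), -g.total_score))
    return groups


def call_synteny(
    anchor: SyntenyAnchor,
    cluster_sequence: str,
    search: SimilaritySearch,
    target_clusters: Sequence[PiRNACluster] = (),
    min_exons: int = 4,
    min_rel_size: float = 0.10,
    max_span: int = 1_000_000,
    neighborhood: int = 100_000,
) -> SyntenyCall:
    """Decide synteny of one anchored cluster against a target genome.

    Syntenic iff a single target region gathers at least ``min_exons``
    distinct homologous anchor exons ("more than three" read strictly).
    ``cluster_body_conserved`` reports whether the cluster sequence itself
    retains a hit; ``target_cluster_present`` whether a known target-genome
    cluster lies within ``neighborhood`` of the matched region.
    """
    exons = anchor.exons
    if not exons:
        return SyntenyCall(
            cluster=anchor.cluster, n_homologous_exons=0, total_bit_score=0.0,
            syntenic=False, cluster_body_conserved=False,
            target_cluster_present=False, target_region=None,
            diagnostic="no flanking exons on the chromosome",
        )
    exon_hits = [search.search(e.sequence, min_rel_size=min_rel_size)
                 for e in exons]
    groups = group_hits(exon_hits, max_span=max_span)
    body_hits = search.search(cluster_sequence, min_rel_size=min_rel_size)
    body_conserved = bool(body_hits)
    if not groups:
        return SyntenyCall(
            cluster=anchor.cluster, n_homologous_exons=0, total_bit_score=0.0,
            syntenic=False, cluster_body_conserved=body_conserved,
            target_cluster_present=False, target_region=None,
            diagnostic="no exon hits in target",
        )
    top = groups[0]
    n_hom = len(top.exon_indices)
    region = (top.chrom, top.target_start, top.target_end)
    near = any(
        c.chrom == top.chrom
        and min(c.end, top.target_end + neighborhood)
        > max(c.start, top.target_start - neighborhood)
        for c in target_clusters
    )
    return SyntenyCall(
        cluster=anchor.cluster,
        n_homologous_exons=n_hom,
        total_bit_score=top.total_score,
        syntenic=n_hom >= min_exons,
        cluster_body_conserved=body_conserved,
        target_cluster_present=near,
        target_region=region,
    )


def synteny_screen(
    genome_a: dict[str, str],
    clusters_a: Sequence[PiRNACluster],
    genes_a: Sequence[GeneModel],
    genome_b: dict[str, str],
    clusters_b: Sequence[PiRNACluster] = (),
    n_flank: int = 10,
    min_exons: int = 4,
    min_rel_size: float = 0.10,
    min_cluster_length: int = 1000,
    **search_kwargs,
) -> tuple[list[SyntenyCall], pd.DataFrame]:
    """Run the full anchor-and-search screen for every eligible A-cluster."""
    search = SimilaritySearch(genome_b, **search_kwargs)
    calls = []
    for c in clusters_a:
        if c.length <= min_cluster_length:
            continue
        anchor = flanking_exons(
            c, genes_a, genome_a, n=n_flank,
            min_cluster_length=min_cluster_length,
        )
        body = genome_a[c.chrom][c.start : c.end]
        calls.append(
            call_synteny(
                anchor, body, search, target_clusters=clusters_b,
                min_exons=min_exons, min_rel_size=min_rel_size,
            )
        )
    table = pd.DataFrame(
        [
            {
                "chrom": k.cluster.chrom,
                "start": k.cluster.start,
                "end": k.cluster.end,
                "n_homologous_exons": k.n_homologous_exons,
                "total_bit_score": k.total_bit_score,
                "syntenic": k.syntenic,
                "cluster_body_conserved": k.cluster_body_conserved,
                "target_cluster_present": k.target_cluster_present,
            }
            for k in calls
        ]
    )
    return calls, table
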