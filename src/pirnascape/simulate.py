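"""Synthetic genomes, annotations, and gonadal small-RNA reads with known truth.

The generator plants, into a random background genome: transposable-element
families (copies of a random consensus mutated under a Kimura two-parameter
substitution process to a chosen divergence), genes with exon/intron
structure, and piRNA clusters that emit 24-32 nt reads with controlled 1U
fraction, 10A fraction, ping-pong pairing fraction, and strand mix.
Everything is deterministic under a fixed seed and accompanied by a
machine-readable truth set.

Because emitted reads are exact genome substrings, the ping-pong geometry
ties the two base-bias knobs together: a secondary read's position-10 base
is the complement of its primary partner's 5' base.  The generator therefore
plants the 5' base of each read locus (T with probability ``u1_fraction``)
and the base 9 nt downstream of it (A with probability ``a10_fraction``);
bulk position-1 U and position-10 A frequencies over all reads then recover
both knobs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from ._seq import decode, encode, random_dna, revcomp, TRANSITION_PARTNER
from .composition import GeneModel, RepeatAnnotation
from .filters import SmallRNARead
from .landscape import copy_divergence, kimura2p


class ConfigurationError(ValueError):
    """Simulation configuration cannot be realized."""


@dataclass(frozen=True)
class TEFamilySpec:
    """One TE family: `copy_number` copies of a `consensus_length`-bp
    consensus, each mutated to `target_divergence` substitutions/site with
    transition:transversion odds `tstv_ratio`:1."""

    name: str
    repeat_class: str  # DNA, LINE, SINE, LTR, satellite, simple, unknown
    consensus_length: int
    copy_number: int
    target_divergence: float = 0.0
    tstv_ratio: float = 2.0
    superfamily: str = ""

    def __post_init__(self):
        if self.target_divergence < 0:
            raise ConfigurationError("target_divergence must be >= 0")
        if self.tstv_ratio <= 0:
            raise ConfigurationError("tstv_ratio must be positive")
        if self.consensus_length < 1 or self.copy_number < 0:
            raise ConfigurationError("bad family geometry")


@dataclass(frozen=True)
class GeneSpec:
    n_exons: int
    exon_length: int
    intron_length: int

    @property
    def total_length(self) -> int:
        return self.n_exons * self.exon_length + max(0, self.n_exons - 1) * self.intron_length


@dataclass(frozen=True)
class ClusterSpec:
    """A piRNA cluster emitting `depth` reads from `n_read_loci` distinct
    5' positions.  `start=None` lets the allocator place the cluster in
    free space; an explicit start plants it there even over other
    features."""

    length: int
    n_read_loci: int
    depth: int
    pingpong_fraction: float = 0.0
    u1_fraction: float = 0.25
    a10_fraction: float = 0.25
    strand_plus_fraction: float = 0.5
    start: int | None = None

    def __post_init__(self):
        for name in ("pingpong_fraction", "u1_fraction", "a10_fraction",
                     "strand_plus_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1]")
        if self.n_read_loci < 1 or self.depth < 1 or self.length < 1:
            raise ConfigurationError("bad cluster geometry")


@dataclass(frozen=True)
class SimConfig:
    genome_length: int
    rng_seed: int
    te_families: tuple[TEFamilySpec, ...] = ()
    genes: tuple[GeneSpec, ...] = ()
    clusters: tuple[ClusterSpec, ...] = ()
    multimap_copies: int = 0
    read_length_range: tuple[int, int] = (24, 32)
    chrom: str = "chr1"
    #: free space kept around every allocator-placed feature, so planted
    #: features are resolvable as distinct entities by interval detectors
    feature_margin: int = 0

    def __post_init__(self):
        object.__setattr__(self, "te_families", tuple(self.te_families))
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "clusters", tuple(self.clusters))
        lo, hi = self.read_length_range
        if lo > hi or lo < 1:
            raise ConfigurationError("bad read_length_range")
        max_len = hi
        for c in self.clusters:
            if c.length < max_len:
                raise ConfigurationError(
                    f"cluster of {c.length} bp shorter than max read length {max_len}"
                )


@dataclass(frozen=True)
class PlantedLocus:
    five_prime: int
    strand: str
    has_partner: bool


@dataclass
class PlantedCluster:
    chrom: str
    start: int
    end: int
    spec_index: int
    loci: list[PlantedLocus]
    read_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ReadOrigin:
    cluster_index: int
    locus_index: int
    role: str  # primary | partner
    chrom: str
    five_prime: int
    strand: str


@dataclass
class TruthSet:
    """Ground truth for one simulated dataset."""

    te_copies: list[RepeatAnnotation]
    clusters: list[PlantedCluster]
    genes: list[GeneModel]
    multimap_regions: list[tuple[str, int, int]]
    read_origins: dict[str, ReadOrigin] = field(default_factory=dict)

    def category_base_counts(self) -> dict[str, int]:
        """Planted bases per repeat category (for composition accounting)."""
        acc: dict[str, int] = {}
        for te in self.te_copies:
            acc[te.category] = acc.get(te.category, 0) + (te.end - te.start)
        return acc


class _FreeSpace:
    """Non-overlapping placement of features on [0, length)."""

    def __init__(self, length: int):
        self.free: list[tuple[int, int]] = [(0, length)]

    def claim(self, start: int, end: int) -> None:
        new = []
        for s, e in self.free:
            if e <= start or s >= end:
                new.append((s, e))
                continue
            if s < start:
                new.append((s, start))
            if e > end:
                new.append((end, e))
        self.free = new

    def place(self, need: int, rng: np.random.Generator, margin: int = 0) -> int:
        padded = need + 2 * margin
        cands = [(s, e) for s, e in self.free if e - s >= padded]
        if not cands:
            raise ConfigurationError(
                f"no free segment of {padded} bp left in the genome"
            )
        weights = np.array([e - s - padded + 1 for s, e in cands], dtype=float)
        i = int(rng.choice(len(cands), p=weights / weights.sum()))
        s, e = cands[i]
        start = s + margin + int(rng.integers(0, e - s - padded + 1))
        self.claim(start - margin, start + need + margin)
        return start


def _solved_pq(d: float, kappa: float) -> tuple[float, float]:
    """Expected (P, Q) proportions with P:Q = kappa:1 and K2P(P, Q) = d."""
    if d == 0:
        return 0.0, 0.0
    q_max = 1.0 / (2.0 * kappa + 1.0)

    def f(q: float) -> float:
        return kimura2p(kappa * q, q) - d

    q = brentq(f, 1e-12, q_max * (1 - 1e-9))
    return kappa * q, q


def mutate_copy(
    consensus: str, d: float, kappa: float, rng: np.random.Generator
) -> str:
    """Mutate a consensus so the expected K2P distance to it equals ``d``.

    Per site, independently: a transition with probability P and each of
    the two transversions with probability Q/2, where (P, Q) solve
    K2P(P, Q) = d under transition:transversion odds ``kappa``:1.  Length
    is preserved; no indels.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if d == 0:
        return consensus
    P, Q = _solved_pq(d, kappa)
    codes = encode(consensus).copy()
    u = rng.random(len(codes))
    valid = codes < 4
    ts_mask = (u < P) & valid
    tv_mask = (u >= P) & (u < P + Q) & valid
    codes[ts_mask] = TRANSITION_PARTNER[codes[ts_mask]]
    if tv_mask.any():
        # each base has two transversion partners; pick one uniformly
        orig = codes[tv_mask]
        pick = rng.integers(0, 2, size=len(orig))
        # partners: for A(0),G(2) -> C(1),T(3); for C(1),T(3) -> A(0),G(2)
        purine = (orig == 0) | (orig == 2)
        out = np.where(purine, np.where(pick == 0, 1, 3), np.where(pick == 0, 0, 2))
        codes[tv_mask] = out.astype(np.uint8)
    return decode(codes)


def make_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[RepeatAnnotation], list[GeneModel], TruthSet]:
    """Build the genome, annotations, and truth set from a configuration.

    Deterministic given ``config.rng_seed``.  Annotations use 0-based
    half-open intervals.  Read sequences are emitted separately by
    :func:`simulate_pirna_reads`.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(2)[0])
    L = config.genome_length
    genome = bytearray(random_dna(rng, L), "ascii")
    space = _FreeSpace(L)
    chrom = config.chrom

    # clusters are the largest planted features, so their intervals are
    # reserved first: random placement of many small TE copies would
    # otherwise fragment free space below the largest request
    cluster_starts: list[int] = []
    for c in config.clusters:
        if c.start is not None:
            if c.start < 0 or c.start + c.length > L:
                raise ConfigurationError("fixed cluster outside the genome")
            space.claim(c.start, c.start + c.length)
            cluster_starts.append(c.start)
        else:
            cluster_starts.append(
                space.place(c.length, rng, config.feature_margin)
            )

    repeats: list[RepeatAnnotation] = []
    for fam in config.te_families:
        consensus = random_dna(rng, fam.consensus_length)
        for _ in range(fam.copy_number):
            start = space.place(fam.consensus_length, rng, config.feature_margin)
            copy = mutate_copy(consensus, fam.target_divergence, fam.tstv_ratio, rng)
            genome[start : start + fam.consensus_length] = copy.encode("ascii")
            realized = copy_divergence(copy, consensus).K
            repeats.append(
                RepeatAnnotation(
                    chrom=chrom, start=start, end=start + fam.consensus_length,
                    repeat_class=fam.repeat_class, superfamily=fam.superfamily,
                    family=fam.name, divergence=realized,
                )
            )

    genes: list[GeneModel] = []
    for gi, gs in enumerate(config.genes):
        start = space.place(gs.total_length, rng, config.feature_margin)
        exons = []
        pos = start
        for _ in range(gs.n_exons):
            exons.append((pos, pos + gs.exon_length))
            pos += gs.exon_length + gs.intron_length
        genes.append(
            GeneModel(
                chrom=chrom, start=start, end=start + gs.total_length,
                strand="+", gene_id=f"gene{gi}", exons=tuple(exons),
            )
        )

    max_len = config.read_length_range[1]
    planted_clusters: list[PlantedCluster] = []
    for ci, cs in enumerate(config.clusters):
        start = cluster_starts[ci]
        end = start + cs.length
        lo = start + max_len
        hi = end - max_len  # inclusive bound for 5' positions, both strands
        n_positions = hi - lo + 1
        if n_positions < cs.n_read_loci:
            raise ConfigurationError(
                f"cluster {ci}: {cs.n_read_loci} loci do not fit in "
                f"{cs.length} bp with {max_len} nt reads"
            )
        positions = np.sort(
            rng.choice(np.arange(lo, hi + 1), size=cs.n_read_loci, replace=False)
        )
        loci = []
        for p in positions:
            p = int(p)
            strand = "+" if rng.random() < cs.strand_plus_fraction else "-"
            has_partner = rng.random() < cs.pingpong_fraction
            if strand == "+":
                _plant_base(genome, p, "T", cs.u1_fraction, rng)
                _plant_base(genome, p + 9, "A", cs.a10_fraction, rng)
            else:
                _plant_base(genome, p, "A", cs.u1_fraction, rng)
                _plant_base(genome, p - 9, "T", cs.a10_fraction, rng)
            loci.append(PlantedLocus(five_prime=p, strand=strand,
                                     has_partner=has_partner))
        planted_clusters.append(
            PlantedCluster(chrom=chrom, start=start, end=end,
                           spec_index=ci, loci=loci)
        )

    multimap_regions: list[tuple[str, int, int]] = []
    if config.multimap_copies > 0:
        if not planted_clusters:
            raise ConfigurationError("multimap_copies set but no clusters planted")
        src = planted_clusters[0]
        template = bytes(genome[src.start : src.end])
        for _ in range(config.multimap_copies):
            start = space.place(len(template), rng, config.feature_margin)
            genome[start : start + len(template)] = template
            multimap_regions.append((chrom, start, start + len(template)))

    truth = TruthSet(
        te_copies=repeats, clusters=planted_clusters, genes=genes,
        multimap_regions=multimap_regions,
    )
    return {chrom: genome.decode("ascii")}, repeats, genes, truth


def _plant_base(
    genome: bytearray, pos: int, base: str, prob: float, rng: np.random.Generator
) -> None:
    """Set genome[pos] to ``base`` with probability ``prob``, otherwise to a
    uniformly random *other* base (so the realized rate equals ``prob``)."""
    if rng.random() < prob:
        genome[pos] = ord(base)
    else:
        others = [b for b in b"ACGT" if b != ord(base)]
        genome[pos] = others[int(rng.integers(0, 3))]


def simulate_pirna_reads(
    genome: dict[str, str],
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[SmallRNARead]:
    """Emit collapsed reads from the planted clusters.

    Each planted locus yields a primary read; loci flagged with a partner
    also yield an opposite-strand read whose 5' end overlaps the primary's
    by exactly 10 nt.  Lengths are uniform over ``read_length_range``;
    per-cluster total copy count equals the cluster's ``depth`` (every read
    carries count >= 1).  Read origins are recorded in ``truth``.
    """
    lo_len, hi_len = config.read_length_range
    reads: list[SmallRNARead] = []
    for pc in truth.clusters:
        cs = config.clusters[pc.spec_index]
        seq = genome[pc.chrom]
        slots: list[tuple[str, ReadOrigin, str]] = []  # (read_id, origin, sequence)
        for li, locus in enumerate(pc.loci):
            length = int(rng.integers(lo_len, hi_len + 1))
            rid = f"c{pc.spec_index}l{li}p"
            slots.append(
                (
                    rid,
                    ReadOrigin(pc.spec_index, li, "primary", pc.chrom,
                               locus.five_prime, locus.strand),
                    _extract(seq, locus.five_prime, locus.strand, length),
                )
            )
            if locus.has_partner:
                plen = int(rng.integers(lo_len, hi_len + 1))
                if locus.strand == "+":
                    q, pstrand = locus.five_prime + 9, "-"
                else:
                    q, pstrand = locus.five_prime - 9, "+"
                prid = f"c{pc.spec_index}l{li}s"
                slots.append(
                    (
                        prid,
                        ReadOrigin(pc.spec_index, li, "partner", pc.chrom,
                                   q, pstrand),
                        _extract(seq, q, pstrand, plen),
                    )
                )
        if cs.depth < len(slots):
            raise ConfigurationError(
                f"cluster {pc.spec_index}: depth {cs.depth} below the "
                f"{len(slots)} emitted reads"
            )
        counts = rng.multinomial(cs.depth - len(slots),
                                 np.full(len(slots), 1.0 / len(slots))) + 1
        for (rid, origin, rseq), count in zip(slots, counts):
            if rid in truth.read_origins:
                raise ConfigurationError(f"duplicate read id {rid}")
            truth.read_origins[rid] = origin
            pc.read_ids.append(rid)
            reads.append(SmallRNARead(id=rid, sequence=rseq, count=int(count)))
    return reads


def _extract(seq: str, five_prime: int, strand: str, length: int) -> str:
    if strand == "+":
        return seq[five_prime : five_prime + length]
    return revcomp(seq[five_prime - length + 1 : five_prime + 1])


def simulate_dataset(config: SimConfig):
    """Genome + annotations + truth + reads in one deterministic call."""
    genome, repeats, genes, truth = make_genome(config)
    read_rng = np.random.default_rng(
        np.random.SeedSequence(config.rng_seed).spawn(2)[1]
    )
    reads = simulate_pirna_reads(genome, truth, config, read_rng)
    return genome, repeats, genes, truth, reads
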