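"""Mapping rules: seed-anchored mismatch pattern, best-stratum selection,
and density-proportional multimapper reallocation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pirnascape import (
    AlignedRead, GenomeMapper, ReadTooShortError, SmallRNARead,
    reallocate_weights, select_min_mismatch, valid_mismatch_pattern,
)
from pirnascape._seq import encode, random_dna, revcomp


def brute_force_alignments(read_seq, genome, seed_length=18,
                           terminal_protect=2, max_mismatches=2):
    """Exhaustive oracle: slide the read (and its reverse complement) over
    every genome offset and apply the mismatch-pattern rule directly."""
    hits = []
    L = len(read_seq)
    for chrom, seq in genome.items():
        g = encode(seq)
        for pattern, strand in ((read_seq, "+"), (revcomp(read_seq), "-")):
            p = encode(pattern)
            for start in range(len(seq) - L + 1):
                diff = np.nonzero(g[start:start + L] != p)[0]
                if strand == "+":
                    mm = sorted(int(i) + 1 for i in diff)
                else:
                    mm = sorted(L - int(i) for i in diff)
                if valid_mismatch_pattern(L, mm, seed_length,
                                          terminal_protect, max_mismatches):
                    hits.append((chrom, start, strand, tuple(mm)))
    return sorted(hits)


def plant(genome_str, pos, insert):
    return genome_str[:pos] + insert + genome_str[pos + len(insert):]


class TestValidMismatchPattern:
    @pytest.mark.parametrize(
        "length,positions,expected",
        [
            (30, [], True),
            (30, [29], False),       # protected last-two positions
            (30, [30], False),
            (30, [19, 28], True),
            (30, [18, 28], False),   # inside the 18-nt seed
            (30, [5], False),
            (30, [19, 20, 21], False),  # over the 2-mismatch budget
            (24, [19, 22], True),
            (21, [19], True),
        ],
    )
    def test_rule(self, length, positions, expected):
        assert valid_mismatch_pattern(length, positions) is expected


class TestEnumerateAlignments:
    def test_verbatim_read_maps_once_with_zero_mismatches(self, rng):
        g = random_dna(rng, 5_000)
        read_seq = g[1000:1028]
        mapper = GenomeMapper({"chr1": g})
        alns = mapper.enumerate_alignments(SmallRNARead("r1", read_seq))
        plus = [a for a in alns if a.strand == "+"]
        assert len(plus) == 1
        assert (plus[0].start, plus[0].mismatch_positions) == (1000, ())

    def test_mismatch_in_seed_rejected(self, rng):
        g = random_dna(rng, 5_000)
        read_seq = list(g[2000:2028])
        read_seq[4] = {"A": "C"}.get(read_seq[4], "A")  # mismatch at pos 5
        read_seq = "".join(read_seq)
        mapper = GenomeMapper({"chr1": g})
        alns = mapper.enumerate_alignments(SmallRNARead("r1", read_seq))
        assert not any(a.start == 2000 and a.strand == "+" for a in alns)

    def test_two_tail_mismatches_accepted_three_rejected(self, rng):
        """30-nt read differing at positions 20 and 25 accepted; adding a
        third difference at 27 rejects the locus (oracle-verified)."""
        g = random_dna(rng, 5_000)
        base = g[3000:3030]

        def flip(s, pos1):  # pos1 is 1-based read position
            i = pos1 - 1
            return s[:i] + {"A": "C", "C": "A", "G": "T", "T": "G"}[s[i]] + s[i + 1:]

        two = flip(flip(base, 20), 25)
        three = flip(two, 27)
        mapper = GenomeMapper({"chr1": g})
        two_hits = mapper.enumerate_alignments(SmallRNARead("r2", two))
        assert any(
            a.start == 3000 and a.mismatch_positions == (20, 25)
            for a in two_hits
        )
        three_hits = mapper.enumerate_alignments(SmallRNARead("r3", three))
        assert not any(a.start == 3000 and a.strand == "+" for a in three_hits)
        assert [
            (a.chrom, a.start, a.strand, a.mismatch_positions) for a in two_hits
        ] == brute_force_alignments(two, {"chr1": g})

    def test_minus_strand_alignment_found(self, rng):
        g = random_dna(rng, 5_000)
        read_seq = revcomp(g[1500:1527])
        mapper = GenomeMapper({"chr1": g})
        alns = mapper.enumerate_alignments(SmallRNARead("r1", read_seq))
        minus = [a for a in alns if a.strand == "-"]
        assert any(a.start == 1500 for a in minus)

    def test_too_short_read_rejected_with_diagnostic(self, rng):
        g = random_dna(rng, 1_000)
        mapper = GenomeMapper({"chr1": g})
        with pytest.raises(ReadTooShortError):
            mapper.enumerate_alignments(SmallRNARead("r1", "ACGT" * 5))

    def test_agrees_with_exhaustive_oracle(self, rng):
        """Planted multi-locus reads with controlled mismatches on a 50-kb
        genome: the indexed mapper equals the sliding-window oracle."""
        g = random_dna(rng, 50_000)
        # plant a template at three loci, with planted tail differences
        template = random_dna(rng, 28)
        g = plant(g, 5_000, template)
        g = plant(g, 20_000, template)
        mutated = (
            template[:19] + {"A": "G", "C": "T", "G": "A", "T": "C"}[template[19]]
            + template[20:]
        )
        g = plant(g, 35_000, mutated)
        genome = {"chr1": g}
        mapper = GenomeMapper(genome)
        for i, read_seq in enumerate(
            [template, mutated, revcomp(template), random_dna(rng, 26)]
        ):
            got = [
                (a.chrom, a.start, a.strand, a.mismatch_positions)
                for a in mapper.enumerate_alignments(SmallRNARead(f"r{i}", read_seq))
            ]
            assert got == brute_force_alignments(read_seq, genome)

    def test_shrinking_mismatch_budget_never_adds_alignments(self, rng):
        g = {"chr1": random_dna(rng, 20_000)}
        read_seq = g["chr1"][700:728]
        sets = []
        for budget in (2, 1, 0):
            mapper = GenomeMapper(g, max_mismatches=budget)
            alns = mapper.enumerate_alignments(SmallRNARead("r", read_seq))
            sets.append({(a.start, a.strand, a.mismatch_positions) for a in alns})
        assert sets[2] <= sets[1] <= sets[0]


class TestSelectMinMismatch:
    def mk(self, start, mm):
        return AlignedRead("r", "chr1", start, "+", 30, tuple(mm), 1)

    def test_best_stratum_only(self):
        alns = [self.mk(0, []), self.mk(100, [20]), self.mk(200, [21])]
        assert select_min_mismatch(alns) == [self.mk(0, [])]

    def test_ties_all_retained(self):
        alns = [self.mk(100, [20, 25]), self.mk(0, [19, 24])]
        kept = select_min_mismatch(alns)
        assert len(kept) == 2
        assert [a.start for a in kept] == [0, 100]  # deterministic order

    def test_empty(self):
        assert select_min_mismatch([]) == []

    def test_mixed_reads_rejected(self):
        alns = [self.mk(0, []),
                AlignedRead("other", "chr1", 5, "+", 30, (), 1)]
        with pytest.raises(ValueError):
            select_min_mismatch(alns)


class TestReallocateWeights:
    def test_unique_read_keeps_full_count(self):
        a = AlignedRead("u", "chr1", 100, "+", 28, (), count=7)
        out = reallocate_weights([a])
        assert out[0].weight == 7.0

    def test_proportional_split_by_unique_density(self):
        """Count 4 over loci with U = 30 and U = 10 -> weights 3 and 1."""
        uniq1 = AlignedRead("u1", "chr1", 1_000, "+", 28, (), count=30)
        uniq2 = AlignedRead("u2", "chr1", 50_000, "+", 28, (), count=10)
        multi = [
            AlignedRead("m", "chr1", 1_100, "+", 28, (), count=4),
            AlignedRead("m", "chr1", 50_100, "+", 28, (), count=4),
        ]
        out = reallocate_weights([uniq1, uniq2] + multi)
        w = {(a.read_id, a.start): a.weight for a in out}
        assert w[("m", 1_100)] == pytest.approx(3.0)
        assert w[("m", 50_100)] == pytest.approx(1.0)

    def test_uniform_fallback_when_no_unique_neighbors(self):
        multi = [
            AlignedRead("m", "chr1", 100, "+", 28, (), count=5),
            AlignedRead("m", "chr1", 90_000, "+", 28, (), count=5),
        ]
        out = reallocate_weights(multi)
        assert [a.weight for a in out] == [2.5, 2.5]

    def test_window_boundary_inclusive(self):
        uniq = AlignedRead("u", "chr1", 5_000, "+", 28, (), count=8)
        multi = [
            AlignedRead("m", "chr1", 0, "+", 28, (), count=2),       # at -5000
            AlignedRead("m", "chr2", 500, "+", 28, (), count=2),     # no U
        ]
        out = reallocate_weights([uniq] + multi, window=10_000)
        w = {(a.chrom, a.start): a.weight for a in out if a.read_id == "m"}
        assert w[("chr1", 0)] == pytest.approx(2.0)
        assert w[("chr2", 500)] == pytest.approx(0.0)

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=3),   # read group
                st.integers(min_value=0, max_value=2000),
                st.integers(min_value=1, max_value=50),
            ),
            min_size=1, max_size=30,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_weight_conservation(self, rows):
        """Sum of weights equals sum of per-read counts, always."""
        by_read = {}
        for gid, start, count in rows:
            by_read.setdefault(f"r{gid}", []).append((start, count))
        alns = []
        for rid, locs in by_read.items():
            count = locs[0][1]  # one count per read
            seen = set()
            for start, _ in locs:
                if start in seen:
                    continue
                seen.add(start)
                alns.append(AlignedRead(rid, "chr1", start, "+", 28, (), count))
        out = reallocate_weights(alns)
        total_counts = sum(
            {a.read_id: a.count for a in alns}[rid]
            for rid in {a.read_id for a in alns}
        )
        assert sum(a.weight for a in out) == pytest.approx(total_counts)
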