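"""Cluster detection thresholds, merging, and cross-sample comparison."""
import numpy as np
import pytest

from pirnascape import (
    AlignedRead, ChromMap, PiRNACluster, common_clusters, detect_assembly,
    detect_density, location_conservation, map_reads, match_to_truth,
    union_clusters,
)


def plus_at(fp, weight=1.0, rid=None, length=28, chrom="chr1", count=1):
    return AlignedRead(
        read_id=rid or f"p{fp}", chrom=chrom, start=fp, strand="+",
        length=length, count=count, weight=weight,
    )


def spread_loci(first, last, n, **kw):
    """n alignments whose 5' ends span [first, last] evenly."""
    positions = np.linspace(first, last, n).astype(int)
    assert len(set(positions)) == n
    return [plus_at(int(p), rid=f"r{p}", **kw) for p in positions]


class TestDetectDensity:
    def test_dense_cluster_kept(self):
        """12 loci spread over 800 bp -> one cluster at 15 loci/kb."""
        alns = spread_loci(1_000, 1_799, 12)
        out = detect_density(alns)
        assert len(out) == 1
        c = out[0]
        assert (c.start, c.end, c.n_loci) == (1_000, 1_800, 12)
        assert c.density == pytest.approx(15.0)

    def test_nine_loci_rejected_by_min_loci(self):
        assert detect_density(spread_loci(1_000, 1_799, 9)) == []

    def test_low_density_rejected(self):
        """10 loci spread over 20 kb (0.5 loci/kb) -> removed."""
        alns = spread_loci(0, 19_999, 10, )
        # keep gaps below the 5-kb chaining window so it is one candidate
        assert max(np.diff([a.five_prime for a in alns])) < 5_000
        assert detect_density(alns) == []

    def test_candidates_trimmed_to_outermost_loci(self):
        alns = spread_loci(10_000, 10_499, 20)
        c = detect_density(alns)[0]
        assert (c.start, c.end) == (10_000, 10_500)

    def test_raising_min_loci_monotone(self):
        alns = spread_loci(0, 900, 15) + spread_loci(50_000, 50_400, 11)
        counts = [
            len(detect_density(alns, min_loci=k)) for k in (10, 12, 16)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_detected_clusters_non_overlapping(self, pingpong_dataset):
        out = detect_density(pingpong_dataset["alignments"])
        for a, b in zip(out, out[1:]):
            assert a.end <= b.start or a.chrom != b.chrom


class TestDetectAssembly:
    def test_two_fragments_merge_and_pass(self):
        """Two 300-bp fragments 200 bp apart, total weight 80 -> one
        800-bp cluster."""
        frag1 = [plus_at(p, weight=4.0, rid=f"a{p}", length=30)
                 for p in range(1_000, 1_271, 30)]
        frag2 = [plus_at(p, weight=4.0, rid=f"b{p}", length=30)
                 for p in range(1_500, 1_771, 30)]
        out = detect_assembly(frag1 + frag2)
        assert len(out) == 1
        c = out[0]
        assert (c.start, c.end) == (1_000, 1_800)
        assert c.read_weight == pytest.approx(80.0)

    def test_short_merged_cluster_discarded(self):
        """A single 400-bp fragment falls below the 500-bp minimum."""
        alns = [plus_at(p, weight=10.0, rid=f"a{p}", length=30)
                for p in range(1_000, 1_371, 30)]
        assert detect_assembly(alns) == []

    def test_low_weight_cluster_discarded(self):
        alns = [plus_at(p, weight=1.0, rid=f"a{p}", length=30)
                for p in range(1_000, 1_601, 30)]
        assert sum(a.weight for a in alns) < 50
        assert detect_assembly(alns) == []

    def test_min_frag_variant_drops_small_fragments(self):
        """With min_frag=150 a 100-bp fragment near a big one no longer
        contributes (the large-assembly-gap parameterization)."""
        small = [plus_at(4_600, weight=100.0, rid="s1", length=30),
                 plus_at(4_670, weight=100.0, rid="s2", length=30)]
        big = [plus_at(p, weight=10.0, rid=f"b{p}", length=30)
               for p in range(4_950, 5_551, 30)]
        loose = detect_assembly(small + big, min_frag=50)
        strict = detect_assembly(small + big, min_frag=150)
        assert [c.start for c in loose] == [4_600]
        assert [c.start for c in strict] == [4_950]


class TestUnionClusters:
    def mk(self, start, end, method="density", chrom="chr1"):
        return PiRNACluster(chrom=chrom, start=start, end=end, n_loci=10,
                            read_weight=100.0, method=method)

    def test_disjoint_sets_concatenate(self):
        a = [self.mk(0, 1_000)]
        b = [self.mk(5_000, 6_000, "assembly")]
        out = union_clusters(a, b)
        assert [(c.start, c.end) for c in out] == [(0, 1_000), (5_000, 6_000)]
        assert [c.method for c in out] == ["density", "assembly"]

    def test_identical_sets_collapse(self):
        a = [self.mk(0, 1_000)]
        b = [self.mk(0, 1_000, "assembly")]
        out = union_clusters(a, b)
        assert [(c.start, c.end) for c in out] == [(0, 1_000)]
        assert out[0].method == "merged"

    def test_overlapping_clusters_merge_to_union_interval(self):
        out = union_clusters([self.mk(1_000, 2_000)],
                             [self.mk(1_500, 3_000, "assembly")])
        assert [(c.start, c.end, c.method) for c in out] == [
            (1_000, 3_000, "merged")
        ]

    def test_stats_recomputed_from_alignments(self):
        alns = spread_loci(1_000, 2_900, 20)
        out = union_clusters([self.mk(1_000, 2_000)],
                             [self.mk(1_500, 3_000, "assembly")],
                             alignments=alns)
        assert out[0].n_loci == 20
        assert out[0].read_weight == pytest.approx(20.0)


class TestCommonClusters:
    def mk(self, start, end, chrom="chr1"):
        return PiRNACluster(chrom=chrom, start=start, end=end, n_loci=10,
                            read_weight=10.0)

    def test_identical_clusters_are_common(self):
        pairs, only_a, only_b = common_clusters([self.mk(0, 1_000)],
                                                [self.mk(0, 1_000)])
        assert len(pairs) == 1 and not only_a and not only_b
        assert pairs[0][0].sample == "common"

    def test_majority_of_shorter_cluster_rule(self):
        """1,000-bp vs 400-bp overlapping by 300 bp: 300 > 0.5*400 ->
        common under the shorter-cluster reading."""
        a = self.mk(0, 1_000)
        b = self.mk(900, 1_300)
        assert a.overlap(b) == 100  # not common this way
        b2 = self.mk(700, 1_100)
        pairs, _, _ = common_clusters([a], [b2])
        assert len(pairs) == 1

    def test_exact_half_overlap_not_common(self):
        a = self.mk(0, 1_000)
        b = self.mk(800, 1_200)  # overlap 200 = 0.5 * 400, not > half
        pairs, only_a, only_b = common_clusters([a], [b])
        assert not pairs and len(only_a) == 1 and len(only_b) == 1

    def test_reciprocal_mode_stricter(self):
        a = self.mk(0, 1_000)
        b = self.mk(700, 1_100)
        assert common_clusters([a], [b])[0]
        pairs_recip, _, _ = common_clusters([a], [b], reciprocal=True)
        assert not pairs_recip

    def test_zero_overlap_both_specific(self):
        pairs, only_a, only_b = common_clusters(
            [self.mk(0, 1_000)], [self.mk(5_000, 6_000)]
        )
        assert not pairs
        assert only_a[0].sample == "ovary" and only_b[0].sample == "testis"


class TestLocationConservation:
    def mk(self, start, end, chrom="chrA"):
        return PiRNACluster(chrom=chrom, start=start, end=end, n_loci=10,
                            read_weight=10.0)

    def test_mapped_copy_fully_conserved(self):
        a = [self.mk(100, 2_000), self.mk(9_000, 12_000)]
        b = [self.mk(100, 2_000, "chrB"), self.mk(9_000, 12_000, "chrB")]
        cmap = {"chrA": ChromMap(target="chrB")}
        assert location_conservation(a, b, cmap) == 1.0

    def test_empty_target_gives_zero(self):
        a = [self.mk(100, 2_000)]
        assert location_conservation(a, [], {"chrA": ChromMap("chrB")}) == 0.0

    def test_partial_sharing_fraction(self):
        """6 of 10 query clusters have a homologously-placed partner."""
        a = [self.mk(i * 10_000, i * 10_000 + 2_000) for i in range(10)]
        b = [self.mk(i * 10_000, i * 10_000 + 2_000, "chrB") for i in range(6)]
        cmap = {"chrA": ChromMap(target="chrB")}
        assert location_conservation(a, b, cmap) == pytest.approx(0.6)

    def test_affine_coordinate_transform(self):
        a = [self.mk(1_000, 2_000)]
        b = [self.mk(500, 1_100, "chrB")]
        cmap = {"chrA": ChromMap(target="chrB", scale=0.5, offset=0.0)}
        assert location_conservation(a, b, cmap) == 1.0

    def test_unmapped_chromosome_counts_nonconserved(self):
        a = [self.mk(0, 1_000, chrom="chrZ")]
        assert location_conservation(a, a, {}) == 0.0


class TestRecoveryOnSimulation:
    def test_planted_clusters_recovered(self):
        """20 planted clusters (>= 30 loci) on a 500-kb genome: precision
        and recall >= 0.9 at >50% reciprocal overlap."""
        from pirnascape import ClusterSpec, SimConfig
        from pirnascape.simulate import simulate_dataset

        cfg = SimConfig(
            genome_length=500_000, rng_seed=77, feature_margin=5_000,
            clusters=tuple(
                ClusterSpec(length=4_000, n_read_loci=40, depth=500,
                            pingpong_fraction=0.5, u1_fraction=0.8,
                            a10_fraction=0.8)
                for _ in range(20)
            ),
        )
        genome, _, _, truth, reads = simulate_dataset(cfg)
        alignments = map_reads(reads, genome)
        called = detect_density(alignments)
        precision, recall = match_to_truth(
            called, [(c.chrom, c.start, c.end) for c in truth.clusters]
        )
        assert precision >= 0.9
        assert recall >= 0.9
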