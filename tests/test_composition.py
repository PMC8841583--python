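"""Eight-category genome classification, overlap resolution by family
diversity, and fraction attribution."""
import numpy as np
import pytest

from pirnascape import (
    AlignedRead, CATEGORIES, GeneModel, RepeatAnnotation, classify_genome,
    family_diversity, fraction_table, resolve_repeat_overlaps,
)
from pirnascape._seq import random_dna
from pirnascape.simulate import mutate_copy


def rep(start, end, cls="DNA", family="fam", div=None, chrom="chr1"):
    return RepeatAnnotation(chrom=chrom, start=start, end=end,
                            repeat_class=cls, family=family, divergence=div)


def brute_force_resolution(annotations, diversities, genome_length):
    """Per-base oracle: each base goes to the best (diversity, start,
    family) annotation covering it."""
    best = [None] * genome_length
    for ann in annotations:
        key = (diversities[ann.family], ann.start, ann.family)
        for i in range(ann.start, ann.end):
            if best[i] is None or key < best[i][0]:
                best[i] = (key, ann.family)
    return ["" if b is None else b[1] for b in best]


class TestFamilyDiversity:
    def test_identical_copies_zero(self):
        div, reliable = family_diversity(["ACGTACGT"] * 3)
        assert div == 0.0 and reliable

    def test_single_copy_flagged(self):
        div, reliable = family_diversity(["ACGTACGT"])
        assert div == 0.0 and not reliable

    def test_two_copies_single_pairwise_distance(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "ATGTACGTACGTACGTACGT"  # one transition over 20 sites
        div, _ = family_diversity([a, b])
        from pirnascape import kimura2p
        assert div == pytest.approx(kimura2p(0.05, 0.0))

    def test_independent_branches_add(self, rng):
        """Copies mutated independently at d = 0.05 from a consensus sit
        ~2 x 0.05 apart pairwise (simulation oracle)."""
        cons = random_dna(rng, 5_000)
        copies = [mutate_copy(cons, 0.05, 2.0, rng) for _ in range(12)]
        div, _ = family_diversity(copies)
        assert div == pytest.approx(0.10, abs=0.01)


class TestResolveRepeatOverlaps:
    def test_disjoint_annotations_unchanged(self):
        anns = [rep(0, 100, family="a"), rep(200, 300, family="b")]
        out = resolve_repeat_overlaps(anns, {"a": 0.1, "b": 0.2})
        assert [(r.start, r.end, r.family) for r in out] == [
            (0, 100, "a"), (200, 300, "b")
        ]

    def test_low_diversity_wins_contested_bases(self):
        anns = [rep(0, 150, family="old"), rep(100, 250, family="young")]
        out = resolve_repeat_overlaps(anns, {"old": 0.10, "young": 0.02})
        got = sorted((r.start, r.end, r.family) for r in out)
        assert got == [(0, 100, "old"), (100, 250, "young")]

    def test_tie_breaks_by_start_then_name(self):
        anns = [rep(100, 250, family="b"), rep(0, 150, family="a")]
        out = resolve_repeat_overlaps(anns, {"a": 0.05, "b": 0.05})
        got = sorted((r.start, r.end, r.family) for r in out)
        assert got == [(0, 150, "a"), (150, 250, "b")]

    def test_matches_per_base_oracle_on_random_overlaps(self, rng):
        """Three-way and nested overlaps equal brute-force per-base
        assignment on a 100-kb genome."""
        L = 100_000
        fams = {f"f{i}": round(float(rng.random()) * 0.3, 6) for i in range(8)}
        anns = []
        for i in range(60):
            s = int(rng.integers(0, L - 3_000))
            e = s + int(rng.integers(100, 3_000))
            anns.append(rep(s, e, family=f"f{int(rng.integers(0, 8))}"))
        out = resolve_repeat_overlaps(anns, fams)
        oracle = brute_force_resolution(anns, fams, L)
        painted = [""] * L
        for r in out:
            for i in range(r.start, r.end):
                assert painted[i] == "", "output intervals overlap"
                painted[i] = r.family
        assert painted == oracle


class TestClassifyGenome:
    def toy(self):
        """1,000-bp genome: 240 bp DNA transposon, 88 bp retrotransposon,
        gene of 56 bp exon + 300 bp intron."""
        repeats = [rep(0, 240), rep(300, 388, cls="LINE", family="r")]
        genes = [GeneModel(chrom="chr1", start=400, end=756, strand="+",
                           gene_id="g1", exons=((400, 428), (728, 756)))]
        return classify_genome(repeats, genes, {"chr1": 1_000})

    def test_toy_fractions_exact(self):
        fr = self.toy().fractions()
        assert fr["dna_transposon"] == pytest.approx(0.24)
        assert fr["retrotransposon"] == pytest.approx(0.088)
        assert fr["exon"] == pytest.approx(0.056)
        assert fr["intron"] == pytest.approx(0.30)
        assert fr["other"] == pytest.approx(0.316)

    def test_partition_sums_to_one(self):
        assert self.toy().fractions().sum() == pytest.approx(1.0)

    def test_repeat_beats_exon(self):
        repeats = [rep(50, 150)]
        genes = [GeneModel(chrom="chr1", start=100, end=300, strand="+",
                           gene_id="g", exons=((100, 200),))]
        cmap = classify_genome(repeats, genes, {"chr1": 400})
        assert cmap.category_at("chr1", 120) == "dna_transposon"
        assert cmap.category_at("chr1", 220) == "intron"

    def test_empty_annotations_all_other(self):
        cmap = classify_genome([], [], {"chr1": 500})
        assert cmap.fractions()["other"] == 1.0

    def test_exon_outside_gene_rejected(self):
        with pytest.raises(ValueError):
            GeneModel(chrom="chr1", start=100, end=200, strand="+",
                      gene_id="g", exons=((50, 120),))

    def test_overlapping_repeats_rejected(self):
        with pytest.raises(ValueError):
            classify_genome([rep(0, 100), rep(50, 150)], [], {"chr1": 200})

    def test_relabeling_repeat_as_gene_never_changes_repeat_bases(self):
        """Priority property: adding a gene over a repeat leaves every
        repeat-labeled base untouched."""
        repeats = [rep(100, 300)]
        before = classify_genome(repeats, [], {"chr1": 600})
        gene = GeneModel(chrom="chr1", start=50, end=500, strand="+",
                         gene_id="g", exons=((150, 250),))
        after = classify_genome(repeats, [gene], {"chr1": 600})
        for i in range(100, 300):
            assert after.category_at("chr1", i) == before.category_at("chr1", i)

    def test_rle_roundtrip(self):
        cmap = self.toy()
        rle = cmap.rle()
        total = (rle["end"] - rle["start"]).sum()
        assert total == 1_000
        for row in rle.itertuples(index=False):
            assert cmap.category_at(row.chrom, row.start) == row.category


class TestFractionTable:
    def test_pirna_weights_attributed_by_five_prime_base(self):
        repeats = [rep(100, 300, cls="LINE", family="r")]
        cmap = classify_genome(repeats, [], {"chr1": 1_000})
        inside = AlignedRead("a", "chr1", 150, "+", 28, (), 1, weight=3.0)
        outside = AlignedRead("b", "chr1", 500, "+", 28, (), 1, weight=1.0)
        fr = fraction_table(cmap, alignments=[inside, outside])
        assert fr["retrotransposon"] == pytest.approx(0.75)
        assert fr["other"] == pytest.approx(0.25)
        assert fr.sum() == pytest.approx(1.0)

    def test_boundary_spanning_read_single_category(self):
        repeats = [rep(100, 300, cls="LINE", family="r")]
        cmap = classify_genome(repeats, [], {"chr1": 1_000})
        spanning = AlignedRead("s", "chr1", 290, "+", 28, (), 1, weight=1.0)
        fr = fraction_table(cmap, alignments=[spanning])
        assert fr["retrotransposon"] == 1.0  # 5' base rules

    def test_interval_mode_fractions(self):
        repeats = [rep(0, 500)]
        cmap = classify_genome(repeats, [], {"chr1": 1_000})
        fr = fraction_table(cmap, intervals=[("chr1", 250, 750)])
        assert fr["dna_transposon"] == pytest.approx(0.5)
        assert fr.sum() == pytest.approx(1.0)

    def test_planted_weight_fraction_recovered(self, rng):
        """40% of read weight planted in retrotransposon loci is recovered
        within 0.02 (truth-set bookkeeping)."""
        repeats = [rep(10_000, 30_000, cls="LINE", family="r")]
        cmap = classify_genome(repeats, [], {"chr1": 100_000})
        alns = []
        for i in range(400):
            fp = int(rng.integers(10_000, 29_000))
            alns.append(AlignedRead(f"in{i}", "chr1", fp, "+", 28, (), 1, 1.0))
        for i in range(600):
            fp = int(rng.integers(40_000, 99_000))
            alns.append(AlignedRead(f"out{i}", "chr1", fp, "+", 28, (), 1, 1.0))
        fr = fraction_table(cmap, alignments=alns)
        assert fr["retrotransposon"] == pytest.approx(0.40, abs=0.02)

    def test_simulated_genome_fractions_match_truth(self, te_dataset):
        """Planted TE base counts equal classified category fractions."""
        repeats = te_dataset["repeats"]
        genome = te_dataset["genome"]
        cmap = classify_genome(repeats, [], {c: len(s) for c, s in genome.items()})
        truth_counts = te_dataset["truth"].category_base_counts()
        fr = cmap.fractions()
        total = sum(len(s) for s in genome.values())
        assert fr["dna_transposon"] == pytest.approx(
            truth_counts["dna_transposon"] / total
        )
        assert fr["retrotransposon"] == pytest.approx(
            truth_counts["retrotransposon"] / total
        )
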