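# Methods

This note documents the models, parameter choices, and numerical
conventions implemented in `pirnascape`, and what the synthetic-data tests
do and do not establish about real data.

## Candidate selection and mapping

Raw small-RNA reads are collapsed (`id-count` FASTA dialect) with U≡T
throughout. Two filters produce piRNA candidates:

- **ncRNA exclusion** removes a read iff it is an exact substring, in
  either orientation, of any supplied ncRNA reference (miRNA, tRNA, rRNA,
  mRNA). A `max_mismatches` knob relaxes this to near-matches; the default
  is exact because annotation-cascade tools differ in how aggressively
  they match, and exact containment is the reproducible core. Filters are
  idempotent and order-independent.
- **Length window** keeps 24–32 nt inclusive, the canonical piRNA range.

Mapping requires the 5′-most 18 nt (the *seed*) to match the genome
exactly; at most two mismatches are tolerated, only at read positions
19..L−2 — never in the last two positions. The seed length reflects a
zero-mismatch 18-nt anchor as used by short-read aligners run with an
18-nt seed and no seed mismatches; since "seed" is otherwise ambiguous,
the value is explicit and configurable (`GenomeMapper(seed_length=...)`).
Enumeration uses an exact k-mer index over both strands; an exhaustive
sliding-window scan is the test oracle, and the two agree on ≤ 50 kb
genomes.

For each read the minimum-mismatch stratum is retained *in full*. Keeping
a single arbitrary alignment would make multimapper reallocation
meaningless, so the stratum is kept and the read's count is then split
across its loci proportionally to U(locus), the summed count of uniquely
mapping reads whose 5′ ends lie within ±window/2 (window 10 kb by
default) of the locus 5′ end; uniform split if U = 0 everywhere. Weights
sum to the read count exactly, so total weight equals total read count —
an invariant asserted in tests.

## Ping-pong and base-bias statistics

Overlap geometry: a plus-strand 5′ end at *p* and minus-strand 5′ end at
*q ≥ p* on one chromosome overlap by *d = q − p + 1* 5′-anchored bases
(the minus-strand 5′ end is its rightmost genomic base), so the canonical
ping-pong pair has *d = 10*. The overlap score S_d sums weight products
over pairs; scoring indexes 5′ positions per chromosome (linear in reads,
× 30 lookups) and is verified against the O(n²) all-pairs oracle.

Z-scores use the ratios r_d = S_d/ΣS over the background d = 1..30
(read lengths cap meaningful overlaps near 32) with the *population*
standard deviation; ΣS = 0 or sd = 0 yield z ≡ 0 by convention. The
statistic's null behavior is checked with a shuffled null that reassigns
strands and redraws 5′ positions uniformly over each chromosome's
observed 5′ span — note that merely flipping strands at random is *not* a
null: pairs in which neither member flips (a quarter of them) retain
their exact 10-nt geometry and the peak survives.

Base bias extracts the 10 5′-most bases of each alignment in read
orientation (minus strand reverse-complemented), accumulates
weight-weighted frequencies per position, and summarizes position-1 U and
position-10 A. Alignments whose 10-base window runs off the chromosome
are skipped and counted. Length histograms are normalized by
10⁷ / total mapped count.

## Cluster detection and comparison

The density detector realizes the two operative filters — ≥ 1 locus/kb
and ≥ 10 distinct 5′ loci — on candidate regions built by chaining
distinct loci with gaps ≤ 5 kb and trimming to the outermost loci. The
5 kb chaining window is this package's choice (configurable); the two
filters are the meaningful thresholds. The assembly-style detector chains
alignment footprints with gaps ≤ 50 bp into fragments (discarding
< 50 bp; a 150 bp variant suits fragmented assemblies with many short
gaps), then merges fragments with gaps ≤ 250 bp, keeping merged intervals
≥ 500 bp with summed weight ≥ 50. The weight floor re-interprets an
expression floor — undefined without library normalization — as summed
reallocated read weight. Union of the two detectors merges overlapping
calls into their union interval and recomputes counts; an intersect mode
exists.

Two samples' cluster sets are compared by interval overlap: a pair is
common when the overlap exceeds half of the *shorter* cluster (the
permissive reading of "more than half of the overlapped sequences"; a
reciprocal mode requires half of both). Location conservation maps
clusters through a chromosome homology table (optional affine transform)
and reports the fraction with any overlapping partner. Strandedness is
annotated from the weighted strand ratio (≥ 0.8 one-sided →
unidirectional) but never used for filtering.

## Genome composition

Eight categories: DNA transposon, retrotransposon (LINE/SINE/LTR),
satellite, simple repeat, unknown repeat, exon, intron, other. Overlaps
*between repeat annotations* are resolved first by giving contested bases
to the family with the lower diversity score (ties: earlier start, then
name); family diversity is the mean pairwise K2P distance among copies in
the consensus frame — two independent branches of depth d sit ≈ 2d apart,
which the tests confirm. A tree-based diversity would order families the
same way in the regimes tested but needs a tree builder; mean pairwise
distance is reproducible and sufficient for the priority rule.

Classification priority is repeat > exon > intron > other, per base, so
an exon overlapping a transposon counts as transposon. piRNA fractions
attribute each alignment's *weight* to the category under its 5′ base — a
read spanning a boundary gets one category; the convention is documented
because no standard exists. Fractions always partition (sum to 1), and
the interval resolution equals a per-base brute-force oracle on 100 kb
genomes.

## Divergence landscapes and the clock

K2P: K = −½ ln((1−2P−Q)√(1−2Q)), defined for 1−2P−Q > 0 and 1−2Q > 0;
outside that domain a `SaturationError` is raised rather than clamping.
Sites with ambiguous bases are excluded from P/Q counting. No CpG
adjustment is applied (off by default, as the correction is both
assembly- and methylation-state-dependent).

Landscapes assign each copy's full genomic length to the single 0.01-wide
bin containing its K (no smoothing, matching stacked-histogram
landscapes); per-group bin fractions sum exactly to the group's genome
fraction. The clock is linear: age = (K/0.01)·c. The default c = 3.4
reproduces the anchor correspondence 0.05 ↔ 17 mya and 0.10 ↔ 34 mya
(hybridization and speciation of the L/S ancestors); rate estimates of
3.23–3.33 mya per 0.01 for the same taxa are supported by setting
`ClockParams(c=...)`. Note that planted divergences lying exactly on bin
edges split between the two adjacent bins under estimation noise; the
recovery tests therefore require the planted value to lie within the
modal bin's closed range.

## Synteny

Clusters > 1 kb are anchored by the 10 nearest exons on each side (fewer
near chromosome ends). The similarity search is an in-package seeded
(exact 10-mers), X-drop-extended local aligner with fixed default scoring
(match +1, mismatch −2, affine gaps −5/−2 in the contract); extension is
ungapped, which is exact for substitution-only divergence and adequate at
toy scale — a hook allows substituting an external engine for real
genomes. Hits whose aligned query span is below 10% of the query length
are discarded ("relative size" is read as aligned-query-span /
query-length). Homologous exon = exon with ≥ 1 surviving hit; each exon
contributes its best-scoring hit, hits within 1 Mb on one chromosome
group together (the bound is not quantified anywhere authoritative and is
configurable), and order-preservation is flagged. A cluster is syntenic
when one group holds ≥ 4 distinct exons — "more than three" read
literally; ≥ 3 is one keyword away. Scores are summed for ranking
regions, never thresholded. Whether the cluster body itself retains a hit
(`cluster_body_conserved`) separates conserved clusters from turnover at
conserved loci.

## The synthetic-data generator

`simulate` plants into a uniform-random background genome, in this order:
cluster intervals (largest features first, so free space is not
fragmented below their size), TE copies, genes, then per-locus read
bases, then multimapper duplications of the first cluster's sequence.
Placement is uniform over free segments; `feature_margin` (default 0)
keeps that many bases free around each feature so planted features are
resolvable as distinct entities — the cluster-recovery experiments use
5 kb, the density detector's chaining window, because precision/recall
against truth is only well-defined when the truth itself is resolvable.

TE copies evolve by a per-site K2P substitution process with no rate
heterogeneity, CpG effect, or indels: per site, a transition with
probability P and each transversion with probability Q/2, where (P, Q)
solve K2P(P, Q) = d with transition:transversion odds κ:1 (default 2).
The closed-form inversion makes the expected estimated distance equal d
(mean error < 2·10⁻⁴ at 10 kb over 200 replicates), and observed
substitution counts realize the κ:1 odds.

Each cluster emits reads from `n_read_loci` distinct 5′ positions;
strands are drawn with `strand_plus_fraction`, a `pingpong_fraction` of
loci also emit an opposite-strand partner whose 5′ end overlaps the
primary's by exactly 10 nt, lengths are uniform over 24–32 nt, and the
cluster's total copy count equals `depth` with every read ≥ 1. Reads are
exact genome substrings (no sequencing error — mismatch-rule tests plant
controlled mismatches instead), which ties the base-bias knobs together:
a partner's position-10 base is the complement of its primary's 5′ base.
The generator therefore plants the 5′ base of each locus (T with
probability `u1_fraction`) and the base 9 nt downstream (A with
probability `a10_fraction`); with the else-branch forced to a different
base, realized rates equal the knobs exactly, and bulk position-1 U /
position-10 A frequencies over all reads recover both (primaries realize
the 1U knob and partners the 10A knob directly, and symmetrically under
strand swap).

**What passing these tests shows — and does not.** The generator
reproduces the *statistical structure* the analyses assume: controlled
divergence, 5′-overlap geometry, base biases, multimapping by exact
duplication, non-overlapping features. It does not emulate sequencing
error, indel evolution, rate heterogeneity, nested or fragmented TE
copies, chromosome-scale genomes, assembly gaps, or expression-level
realism. Recovery on synthetic data therefore validates the
implementations' correctness against their definitions, not their
robustness to real-assembly artifacts.

## Problem sizes and numerical conventions

Simulation-based tests use genomes of 30–500 kb, read depths of 500–10⁴,
50-copy × 2 kb TE families, and 100–200 Monte-Carlo replicates — sizes at
which every statistic is comfortably estimable and the whole suite runs
in well under a minute per module. Ties in best-stratum selection and
overlap resolution break deterministically (position, then name).
Weights are double precision; conservation invariants are asserted to
1 part in 10⁹. All randomness flows from explicit seeds through
`numpy.random.Generator`; identical configurations reproduce identical
outputs byte-for-byte.

## Known limitations

- The ncRNA exclusion is containment-based, not an annotation cascade;
  heavily edited or trimmed ncRNA fragments would not be caught.
- The density detector is a filter realization, not a probabilistic
  cluster model; very diffuse clusters below 1 locus/kb are invisible by
  design.
- The synteny aligner is ungapped; indel-rich divergence fragments hits
  and will undercount homologous exons on real genomes (substitute a
  gapped engine through the search hook for such data).
- Landscape bins inherit the divergence estimator's variance; families
  planted at bin edges legitimately straddle two bins.
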