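"""Select piRNA candidates and map them with the seed-anchored rule.

Reads are filtered to 24-32 nt after excluding ncRNA matches, mapped with
an 18-nt exact 5' seed (up to two mismatches afterwards, none in the last
two positions), reduced to each read's best stratum, and multimapper
counts are reallocated by local unique-mapper density.
"""
from pirnascape import (
    ClusterSpec, SimConfig, exclude_annotated_rna, length_filter, map_reads,
)
from pirnascape.simulate import simulate_dataset

config = SimConfig(
    genome_length=60_000, rng_seed=7,
    clusters=(ClusterSpec(length=5_000, n_read_loci=60, depth=4_000,
                          pingpong_fraction=0.6, u1_fraction=0.8,
                          a10_fraction=0.8),),
    multimap_copies=1,  # duplicate the cluster once: reads become multimappers
)
genome, _, _, truth, reads = simulate_dataset(config)

# a decoy miRNA reference: any read contained in it would be excluded
mirna = "TGAGGTAGTAGGTTGTATAGTTTTAGGGTCACACCCACCACTGGGAGATAACTATACAA"
candidates = length_filter(exclude_annotated_rna(reads, [mirna]))
print(f"{len(candidates)} of {len(reads)} reads kept as piRNA candidates")

alignments = map_reads(candidates, genome, window=10_000)
total_weight = sum(a.weight for a in alignments)
total_count = sum(r.count for r in candidates)
multi = {a.read_id for a in alignments if a.weight < a.count}
print(f"{len(alignments)} alignments; weight {total_weight:.1f} "
      f"= read count {total_count} (conserved exactly)")
print(f"{len(multi)} reads map to the duplicated cluster copy as well; "
      "their counts were split by nearby unique-mapper density")
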