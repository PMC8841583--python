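"""Decide whether piRNA clusters sit at conserved loci across genomes.

Ten exons on each side of a cluster anchor it; anchors are searched
against the target genome and a cluster is syntenic when at least four
anchor exons land together.  Separately, the cluster body itself is
searched — "syntenic but body not conserved" is the signature of cluster
turnover at a conserved locus.
"""
import numpy as np

from pirnascape import GeneModel, PiRNACluster, synteny_screen
from pirnascape._seq import random_dna
from pirnascape.simulate import mutate_copy

rng = np.random.default_rng(5)
up = [(10_000 + i * 1_000, 10_200 + i * 1_000) for i in range(12)]
cl_start = up[-1][1] + 2_000
cluster = PiRNACluster(chrom="chr1", start=cl_start, end=cl_start + 3_000,
                       n_loci=30, read_weight=200.0)
down = [(cluster.end + 2_000 + i * 1_000, cluster.end + 2_200 + i * 1_000)
        for i in range(12)]
genome_a = {"chr1": random_dna(rng, down[-1][1] + 10_000)}
genes = [GeneModel("chr1", up[0][0], up[-1][1], "+", "gL", tuple(up)),
         GeneModel("chr1", down[0][0], down[-1][1], "+", "gR", tuple(down))]

# target 1: the same genome (self-comparison)
calls, _ = synteny_screen(genome_a, [cluster], genes, genome_a, [cluster])
k = calls[0]
print(f"self: syntenic={k.syntenic} with {k.n_homologous_exons} homologous "
      f"exons, body conserved={k.cluster_body_conserved}")

# target 2: flanks kept, cluster body replaced (turnover)
seq = genome_a["chr1"]
turnover = {"chr1": seq[:cluster.start] + random_dna(rng, cluster.length)
            + seq[cluster.end:]}
k = synteny_screen(genome_a, [cluster], genes, turnover)[0][0]
print(f"turnover: syntenic={k.syntenic}, "
      f"body conserved={k.cluster_body_conserved} "
      "(the locus survives, the cluster does not)")

# target 3: whole genome diverged at 0.3 substitutions/site
far = {"chr1": mutate_copy(seq, 0.3, 2.0, rng)}
k = synteny_screen(genome_a, [cluster], genes, far)[0][0]
print(f"diverged 0.3 subs/site: syntenic={k.syntenic} "
      f"({k.n_homologous_exons} exons still detected)")
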