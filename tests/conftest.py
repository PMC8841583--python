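import numpy as np
import pytest

from pirnascape import (
    ClusterSpec, SimConfig, TEFamilySpec, GeneSpec, map_reads,
)
from pirnascape.simulate import simulate_dataset


@pytest.fixture(scope="session")
def pingpong_dataset():
    """Simulated dataset with a strong planted ping-pong signal.

    Depth 10,000; ping-pong fraction 0.8; 1U and 10A fractions 0.8.
    Shared across signature-recovery tests (read-only).
    """
    cfg = SimConfig(
        genome_length=80_000,
        rng_seed=42,
        clusters=(
            ClusterSpec(length=8_000, n_read_loci=150, depth=10_000,
                        pingpong_fraction=0.8, u1_fraction=0.8,
                        a10_fraction=0.8),
        ),
    )
    genome, repeats, genes, truth, reads = simulate_dataset(cfg)
    alignments = map_reads(reads, genome)
    return {
        "config": cfg, "genome": genome, "truth": truth,
        "reads": reads, "alignments": alignments,
    }


@pytest.fixture(scope="session")
def te_dataset():
    """Toy genome with TE families planted at three divergences."""
    fams = (
        TEFamilySpec("young", "DNA", 2_000, 50, 0.02, superfamily="Kolobok"),
        TEFamilySpec("mid", "DNA", 2_000, 50, 0.05, superfamily="hAT"),
        TEFamilySpec("old", "LINE", 2_000, 50, 0.12, superfamily="L1"),
    )
    cfg = SimConfig(genome_length=500_000, rng_seed=11, te_families=fams)
    genome, repeats, genes, truth, _ = simulate_dataset(cfg)
    return {"config": cfg, "genome": genome, "repeats": repeats,
            "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
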