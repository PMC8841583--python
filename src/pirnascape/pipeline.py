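"""End-to-end orchestration: simulate (or load), filter, map, and analyze.

Each stage writes standard-format outputs into the run directory and a JSON
manifest captures every parameter, the seed, and input checksums, so a run
is reproducible bit-for-bit from its manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .align import map_reads
from .clusters import detect_assembly, detect_density, union_clusters
from .composition import classify_genome, fraction_table, resolve_repeat_overlaps
from .filters import exclude_annotated_rna, length_filter
from .landscape import ClockParams, landscape_from_annotations
from .pingpong import base_bias, length_histogram, normalize_counts, pingpong_profile
from .simulate import SimConfig, simulate_dataset

logger = logging.getLogger("pirnascape")

STAGES = ("simulate", "filter", "align", "signature", "clusters",
          "composition", "landscape")


@dataclass
class PipelineConfig:
    """All stage parameters, with the analysis defaults.

    Defaults: 24-32 nt length window; 18-nt zero-mismatch seed with a
    2-mismatch budget outside seed and last two positions; 10 kb
    reallocation window; cluster filters 1 locus/kb and 10 loci; assembly
    chaining 50/50 then merge 500/250 with weight floor 50; common-cluster
    overlap fraction 0.5; landscape bin 0.01 with clock 3.4 mya per 0.01;
    10 flanking exons, >=4 homologous exons, 10% relative hit size.
    """

    sim: SimConfig | None = None
    genome_path: str | None = None
    reads_path: str | None = None
    ncrna_path: str | None = None
    min_len: int = 24
    max_len: int = 32
    realloc_window: int = 10_000
    cluster_window: int = 5_000
    min_density: float = 1.0
    min_loci: int = 10
    asm_min_frag: int = 50
    asm_gap: int = 50
    asm_min_len: int = 500
    asm_merge_gap: int = 250
    asm_min_weight: float = 50.0
    common_min_frac: float = 0.5
    bin_width: float = 0.01
    clock_c: float = 3.4
    flank_n: int = 10
    synteny_min_exons: int = 4
    min_rel_size: float = 0.10
    rng_seed: int = 0
    sample: str = "unlabeled"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(
    config: PipelineConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Execute the requested stages in order and write a run manifest.

    Returns the manifest dict.  A stage failure raises :class:`StageError`
    without overwriting outputs of earlier stages.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": _serializable(config),
        "stages": list(stages),
        "outputs": {},
        "checksums": {},
    }

    genome = repeats = genes = truth = None
    reads = None

    def record(name: str, path: Path):
        manifest["outputs"][name] = str(path)
        manifest["checksums"][name] = _checksum(path)

    try:
        if "simulate" in stages:
            if config.sim is None:
                raise ValueError("simulate stage requires a SimConfig")
            genome, repeats, genes, truth, reads = simulate_dataset(config.sim)
            io.write_fasta(genome, out / "genome.fa")
            io.write_repeats_bed(repeats, out / "repeats.bed")
            io.write_gff3(genes, out / "genes.gff3")
            io.write_reads(reads, out / "reads.fa")
            io.write_truth(truth, out / "truth.tsv")
            for name in ("genome.fa", "repeats.bed", "genes.gff3",
                         "reads.fa", "truth.tsv"):
                record(name, out / name)
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise StageError("simulate", e) from e

    if genome is None and config.genome_path:
        genome = io.read_fasta(config.genome_path)
        manifest["checksums"]["genome_input"] = _checksum(Path(config.genome_path))
    if reads is None and config.reads_path:
        reads = io.read_reads(config.reads_path)
        manifest["checksums"]["reads_input"] = _checksum(Path(config.reads_path))
    if repeats is None and (out / "repeats.bed").exists():
        repeats = io.read_repeats_bed(out / "repeats.bed")
    if genes is None and (out / "genes.gff3").exists():
        genes = io.read_gff3_genes(out / "genes.gff3")

    try:
        if "filter" in stages:
            if reads is None:
                raise ValueError("no reads available")
            ncrna = (
                list(io.read_fasta(config.ncrna_path).values())
                if config.ncrna_path else []
            )
            reads = exclude_annotated_rna(reads, ncrna)
            reads = length_filter(reads, config.min_len, config.max_len)
            io.write_reads(reads, out / "reads.filtered.fa")
            record("reads.filtered.fa", out / "reads.filtered.fa")
    except StageError:
        raise
    except Exception as e:
        raise StageError("filter", e) from e

    alignments = None
    try:
        if "align" in stages:
            if genome is None or reads is None:
                raise ValueError("align stage needs a genome and reads")
            alignments = map_reads(reads, genome, window=config.realloc_window)
            io.write_alignments(alignments, out / "alignments.tsv")
            io.write_alignments_bed(alignments, out / "alignments.bed")
            record("alignments.tsv", out / "alignments.tsv")
    except StageError:
        raise
    except Exception as e:
        raise StageError("align", e) from e

    if alignments is None and (out / "alignments.tsv").exists():
        alignments = io.read_alignments(out / "alignments.tsv")

    try:
        if "signature" in stages:
            if alignments is None or genome is None:
                raise ValueError("signature stage needs alignments and a genome")
            profile = pingpong_profile(alignments)
            profile.to_csv(out / "pingpong_profile.tsv", sep="\t", index=False)
            bias = base_bias(alignments, genome)
            bias.frequencies.to_csv(out / "base_bias.tsv", sep="\t")
            hist = length_histogram(alignments)
            total = float(sum(a.weight for a in alignments))
            normalize_counts(hist, total).rename("normalized").to_frame().to_csv(
                out / "length_histogram.tsv", sep="\t"
            )
            for name in ("pingpong_profile.tsv", "base_bias.tsv",
                         "length_histogram.tsv"):
                record(name, out / name)
    except StageError:
        raise
    except Exception as e:
        raise StageError("signature", e) from e

    cluster_set = None
    try:
        if "clusters" in stages:
            if alignments is None:
                raise ValueError("clusters stage needs alignments")
            dens = detect_density(
                alignments, window=config.cluster_window,
                min_density=config.min_density, min_loci=config.min_loci,
                sample=config.sample,
            )
            asm = detect_assembly(
                alignments, min_frag=config.asm_min_frag, gap=config.asm_gap,
                min_len=config.asm_min_len, merge_gap=config.asm_merge_gap,
                min_weight=config.asm_min_weight, sample=config.sample,
            )
            cluster_set = union_clusters(dens, asm, alignments=alignments)
            io.write_clusters(cluster_set, out / "clusters.tsv")
            io.write_clusters_bed(cluster_set, out / "clusters.bed")
            record("clusters.tsv", out / "clusters.tsv")
    except StageError:
        raise
    except Exception as e:
        raise StageError("clusters", e) from e

    category_map = None
    try:
        if "composition" in stages:
            if genome is None or repeats is None:
                raise ValueError("composition stage needs a genome and repeats")
            fams: dict[str, list] = {}
            for r in repeats:
                fams.setdefault(r.family, []).append(r)
            diversities = {
                fam: (
                    float(np.mean([r.divergence for r in rows])) * 2
                    if all(r.divergence is not None for r in rows) else 0.0
                )
                for fam, rows in fams.items()
            }
            resolved = resolve_repeat_overlaps(repeats, diversities)
            lengths = {c: len(s) for c, s in genome.items()}
            category_map = classify_genome(resolved, genes or [], lengths)
            table = pd.DataFrame({"genome": fraction_table(category_map)})
            if alignments is not None:
                table["pirna_weight"] = fraction_table(
                    category_map, alignments=alignments
                )
            if cluster_set:
                table["pirna_clusters"] = fraction_table(
                    category_map,
                    intervals=[(c.chrom, c.start, c.end) for c in cluster_set],
                )
            table.to_csv(out / "composition.tsv", sep="\t")
            record("composition.tsv", out / "composition.tsv")
    except StageError:
        raise
    except Exception as e:
        raise StageError("composition", e) from e

    try:
        if "landscape" in stages:
            if genome is None or repeats is None:
                raise ValueError("landscape stage needs a genome and repeats")
            genome_length = sum(len(s) for s in genome.values())
            clock = ClockParams(c=config.clock_c)
            for group_by in ("class", "superfamily"):
                ls = landscape_from_annotations(
                    repeats, genome_length, group_by=group_by,
                    bin_width=config.bin_width, clock=clock,
                )
                ls.to_csv(out / f"landscape_{group_by}.tsv", sep="\t", index=False)
                record(f"landscape_{group_by}.tsv", out / f"landscape_{group_by}.tsv")
    except StageError:
        raise
    except Exception as e:
        raise StageError("landscape", e) from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _serializable(config: PipelineConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=str))
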