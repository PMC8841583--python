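"""Readers and writers for the standard formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; collapsed small-RNA reads use the common
"id-count" FASTA header dialect (``>read7-123`` means 123 copies).
Alignments travel as a documented TSV (one alignment per row), clusters as
BED6 plus extra TSV columns, repeats as RepeatMasker ``.out`` or BED, and
gene models as GFF3.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignedRead
from .clusters import PiRNACluster
from .composition import GeneModel, RepeatAnnotation
from .filters import SmallRNARead
from .simulate import TruthSet


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_indexed(path: str | Path) -> dict[str, str]:
    """Genome access via a faidx index — preferable for chromosome-scale
    FASTA where a full in-memory parse is wasteful."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


_ID_COUNT = re.compile(r"^(?P<id>.*)-(?P<count>\d+)$")


def read_reads(path: str | Path, fmt: str | None = None) -> list[SmallRNARead]:
    """Read small-RNA reads from FASTA (id-count dialect honored) or FASTQ."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        m = _ID_COUNT.match(rec.id) if fmt == "fasta" else None
        if m:
            reads.append(
                SmallRNARead(id=m["id"], sequence=str(rec.seq).upper(),
                             count=int(m["count"]))
            )
        else:
            reads.append(SmallRNARead(id=rec.id, sequence=str(rec.seq).upper()))
    return reads


def write_reads(reads: Iterable[SmallRNARead], path: str | Path) -> None:
    """Write collapsed reads as id-count FASTA."""
    records = [
        SeqRecord(Seq(r.sequence), id=f"{r.id}-{r.count}", description="")
        for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------------- alignments

ALIGNMENT_COLUMNS = [
    "read_id", "chrom", "start", "strand", "length", "mismatches",
    "count", "weight",
]


def write_alignments(alignments: Iterable[AlignedRead], path: str | Path) -> None:
    rows = [
        (
            a.read_id, a.chrom, a.start, a.strand, a.length,
            ",".join(map(str, a.mismatch_positions)) or ".",
            a.count, a.weight,
        )
        for a in alignments
    ]
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_alignments(path: str | Path) -> list[AlignedRead]:
    df = pd.read_csv(path, sep="\t", dtype={"mismatches": str})
    out = []
    for row in df.itertuples(index=False):
        mm = () if row.mismatches in (".", "", None) else tuple(
            int(x) for x in str(row.mismatches).split(",")
        )
        out.append(
            AlignedRead(
                read_id=str(row.read_id), chrom=str(row.chrom),
                start=int(row.start), strand=str(row.strand),
                length=int(row.length), mismatch_positions=mm,
                count=int(row.count), weight=float(row.weight),
            )
        )
    return out


def write_alignments_bed(alignments: Iterable[AlignedRead], path: str | Path) -> None:
    """BED6 with the reallocated weight in the score column."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{a.read_id}\t{a.weight:.6g}\t{a.strand}\n"
            )


# ------------------------------------------------------------------- clusters

CLUSTER_COLUMNS = [
    "chrom", "start", "end", "n_loci", "density", "read_weight", "sample",
    "method", "strandedness",
]


def write_clusters(clusters: Iterable[PiRNACluster], path: str | Path) -> None:
    rows = [
        (
            c.chrom, c.start, c.end, c.n_loci, c.density, c.read_weight,
            c.sample, c.method, c.strandedness,
        )
        for c in clusters
    ]
    pd.DataFrame(rows, columns=CLUSTER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clusters(path: str | Path) -> list[PiRNACluster]:
    df = pd.read_csv(path, sep="\t")
    return [
        PiRNACluster(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            n_loci=int(r.n_loci), read_weight=float(r.read_weight),
            sample=str(r.sample), method=str(r.method),
            strandedness=str(r.strandedness),
        )
        for r in df.itertuples(index=False)
    ]


def write_clusters_bed(clusters: Iterable[PiRNACluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            strand = {"plus": "+", "minus": "-"}.get(c.strandedness, ".")
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\tcluster{i}\t{c.n_loci}\t{strand}\n"
            )


# -------------------------------------------------------------------- repeats

def write_repeats_bed(repeats: Iterable[RepeatAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            name = f"{r.family}|{r.repeat_class}|{r.superfamily}"
            div = "" if r.divergence is None else f"{r.divergence:.6g}"
            score = div or "0"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t{r.strand}\n")


def read_repeats_bed(path: str | Path) -> list[RepeatAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            family, repeat_class, superfamily = (f[3].split("|") + ["", ""])[:3]
            div = float(f[4]) if len(f) > 4 and f[4] not in (".", "0") else None
            out.append(
                RepeatAnnotation(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    repeat_class=repeat_class or "unknown",
                    superfamily=superfamily, family=family, divergence=div,
                    strand=f[5] if len(f) > 5 else "+",
                )
            )
    return out


_RM_CLASS = {
    "DNA": "DNA", "LINE": "LINE", "SINE": "SINE", "LTR": "LTR",
    "RC": "DNA", "Satellite": "satellite", "Simple_repeat": "simple",
    "Low_complexity": "simple", "Unknown": "unknown",
}


def read_repeatmasker_out(path: str | Path) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` table into repeat annotations.

    1-based inclusive coordinates become 0-based half-open; the percent
    divergence column becomes substitutions/site.  Classes outside the
    controlled vocabulary map to ``unknown``.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 14 or not fields[0].replace(".", "").isdigit():
                continue  # header / blank lines
            div = float(fields[1]) / 100.0
            chrom = fields[4]
            start = int(fields[5]) - 1
            end = int(fields[6])
            strand = "+" if fields[8] == "+" else "-"
            family = fields[9]
            cls_fam = fields[10]
            cls = cls_fam.split("/")[0]
            superfamily = cls_fam.split("/")[1] if "/" in cls_fam else ""
            out.append(
                RepeatAnnotation(
                    chrom=chrom, start=start, end=end,
                    repeat_class=_RM_CLASS.get(cls, "unknown"),
                    superfamily=superfamily, family=family,
                    divergence=div, strand=strand,
                )
            )
    return out


# ----------------------------------------------------------------------- GFF3

def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpirnascape\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tpirnascape\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Minimal GFF3 reading: gene + exon features keyed by ID/Parent."""
    gene_rows: dict[str, dict] = {}
    exon_rows: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            if f[2] == "gene":
                gid = attrs.get("ID", f"gene{len(gene_rows)}")
                gene_rows[gid] = {
                    "chrom": f[0], "start": int(f[3]) - 1, "end": int(f[4]),
                    "strand": f[6] if f[6] in "+-" else "+",
                }
            elif f[2] == "exon":
                parent = attrs.get("Parent")
                if parent:
                    exon_rows.setdefault(parent, []).append(
                        (int(f[3]) - 1, int(f[4]))
                    )
    genes = []
    for gid, row in gene_rows.items():
        exons = tuple(sorted(exon_rows.get(gid, [])))
        genes.append(GeneModel(gene_id=gid, exons=exons, **row))
    return genes


# ---------------------------------------------------------------------- truth

def write_truth(truth: TruthSet, path: str | Path) -> None:
    """Flat TSV: one row per planted feature or emitted read."""
    rows = []
    for te in truth.te_copies:
        rows.append(
            ("te_copy", te.chrom, te.start, te.end, te.family,
             te.repeat_class, te.divergence, "", "")
        )
    for g in truth.genes:
        rows.append(("gene", g.chrom, g.start, g.end, g.gene_id, "", "", "", ""))
    for pc in truth.clusters:
        rows.append(
            ("cluster", pc.chrom, pc.start, pc.end, f"cluster{pc.spec_index}",
             "", "", len(pc.loci), ",".join(pc.read_ids))
        )
    for chrom, s, e in truth.multimap_regions:
        rows.append(("multimap_region", chrom, s, e, "", "", "", "", ""))
    for rid, o in truth.read_origins.items():
        rows.append(
            ("read", o.chrom, o.five_prime, "", rid, o.role, "",
             o.cluster_index, o.strand)
        )
    pd.DataFrame(
        rows,
        columns=["kind", "chrom", "start", "end", "name", "info",
                 "divergence", "extra", "detail"],
    ).to_csv(path, sep="\t", index=False)
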