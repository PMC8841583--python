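"""Selection of piRNA-candidate reads from raw small-RNA reads.

Two filters: exclusion of reads matching annotated non-piRNA ncRNAs
(miRNA/tRNA/rRNA/protein-coding references), and the canonical 24-32 nt
piRNA length window.  U and T are treated as identical throughout.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._seq import normalize, revcomp


@dataclass(frozen=True)
class SmallRNARead:
    """A collapsed small-RNA read: unique sequence with its copy count."""

    id: str
    sequence: str
    count: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty read sequence")
        if set(self.sequence.upper()) - set("ACGTUN"):
            raise ValueError(f"invalid alphabet in read {self.id}")
        if self.count < 1:
            raise ValueError("read count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


def _matches_reference(read_seq: str, ref: str, max_mismatches: int) -> bool:
    """Is ``read_seq`` a substring of ``ref`` with <= max_mismatches?"""
    if max_mismatches == 0:
        return read_seq in ref
    n, m = len(ref), len(read_seq)
    for i in range(n - m + 1):
        mm = 0
        window = ref[i : i + m]
        for a, b in zip(read_seq, window):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return True
    return False


def exclude_annotated_rna(
    reads: Iterable[SmallRNARead],
    ncrna_refs: Sequence[str],
    max_mismatches: int = 0,
) -> list[SmallRNARead]:
    """Drop reads contained (either orientation) in any ncRNA reference.

    A read is removed iff its sequence, or its reverse complement, occurs as
    a substring of any reference with at most ``max_mismatches`` mismatches
    (default exact).  Surviving reads pass through unchanged, counts intact.
    """
    refs = [normalize(r) for r in ncrna_refs]
    kept = []
    for read in reads:
        seq = normalize(read.sequence)
        rc = revcomp(seq)
        hit = any(
            _matches_reference(seq, ref, max_mismatches)
            or _matches_reference(rc, ref, max_mismatches)
            for ref in refs
        )
        if not hit:
            kept.append(read)
    return kept


def length_filter(
    reads: Iterable[SmallRNARead], min_len: int = 24, max_len: int = 32
) -> list[SmallRNARead]:
    """Keep reads with min_len <= length <= max_len (both inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    return [r for r in reads if min_len <= len(r) <= max_len]
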