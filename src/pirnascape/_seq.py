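"""Low-level sequence helpers shared across modules.

Sequences are plain upper-case DNA strings (U is normalized to T at the
boundaries).  For numerics we encode A,C,G,T as 0..3 in uint8 arrays; any
other symbol becomes 4 and is excluded from site comparisons.
"""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

# A<->G are transitions (purines), C<->T are transitions (pyrimidines).
_ENC = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i
_ENC[ord("U")] = 3
_ENC[ord("u")] = 3

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

# transition partner under the 0..3 encoding: A<->G (0<->2), C<->T (1<->3)
TRANSITION_PARTNER = np.array([2, 3, 0, 1], dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement (U treated as T's complement partner A)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Upper-case and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence to uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[np.minimum(codes, 4)].tobytes().decode("ascii")


def is_transition(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean mask of transition differences between two code arrays."""
    return (a != b) & (TRANSITION_PARTNER[np.minimum(a, 3)] == b) & (a < 4) & (b < 4)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


class KmerIndex:
    """Exact k-mer lookup over one or more chromosomes via 2-bit codes.

    Positions containing non-ACGT symbols never match.  Lookup returns, for a
    k-mer string, an array of (chrom_id, offset) start positions.
    """

    def __init__(self, genome: dict[str, str], k: int):
        if k < 1 or k > 31:
            raise ValueError("k must be in 1..31")
        self.k = k
        self.chroms = list(genome)
        codes_list = []
        ids_list = []
        offs_list = []
        for cid, chrom in enumerate(self.chroms):
            enc = encode(genome[chrom])
            n = len(enc) - k + 1
            if n <= 0:
                continue
            valid = enc < 4
            win_valid = np.ones(n, dtype=bool)
            # a window is valid iff all k bases are ACGT
            cs = np.concatenate(([0], np.cumsum(~valid)))
            win_valid = (cs[k:] - cs[:-k]) == 0
            kcodes = self._roll(enc, k)
            idx = np.nonzero(win_valid)[0]
            codes_list.append(kcodes[idx])
            ids_list.append(np.full(len(idx), cid, dtype=np.int32))
            offs_list.append(idx.astype(np.int64))
        if codes_list:
            codes = np.concatenate(codes_list)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._ids = np.concatenate(ids_list)[order]
            self._offsets = np.concatenate(offs_list)[order]
        else:
            self._codes = np.empty(0, dtype=np.uint64)
            self._ids = np.empty(0, dtype=np.int32)
            self._offsets = np.empty(0, dtype=np.int64)

    @staticmethod
    def _roll(enc: np.ndarray, k: int) -> np.ndarray:
        """Pack every k-mer of an encoded array into a uint64 (invalid bases
        produce arbitrary codes; callers mask them out)."""
        e = np.minimum(enc, 3).astype(np.uint64)
        n = len(e) - k + 1
        out = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            out = (out << np.uint64(2)) | e[j : j + n]
        return out

    def lookup(self, kmer: str) -> tuple[np.ndarray, np.ndarray]:
        enc = encode(kmer)
        if len(enc) != self.k or (enc >= 4).any():
            return (np.empty(0, dtype=np.int32), np.empty(0, dtype=np.int64))
        code = np.uint64(0)
        for c in enc:
            code = (code << np.uint64(2)) | np.uint64(c)
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._ids[lo:hi], self._offsets[lo:hi]
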