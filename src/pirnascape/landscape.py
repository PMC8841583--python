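"""Transposable-element divergence landscapes on a Kimura two-parameter axis.

A TE copy's divergence from its family consensus is summarized by the K2P
distance K = -1/2 ln((1-2P-Q) sqrt(1-2Q)), where P and Q are the transition
and transversion proportions over compared sites.  Binning copy lengths by K
and normalizing by genome size yields the classic repeat landscape: a proxy
for the age distribution of TE insertions.  A linear molecular clock converts
the substitution axis to million years ago (mya).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import numpy as np
import pandas as pd

from ._seq import encode, is_transition


class SaturationError(ValueError):
    """K2P distance is undefined: substitution proportions too high."""


@dataclass(frozen=True)
class DivergenceEstimate:
    """Transition/transversion proportions and K2P distance for one copy."""

    P: float
    Q: float
    K: float
    sites_compared: int


@dataclass(frozen=True)
class ClockParams:
    """Linear molecular clock: `c` mya per 0.01 substitutions/site.

    The default 3.4 anchors substitution ratios 0.10 and 0.05 to 34 and
    17 mya (speciation and hybridization of the L/S ancestors); rate
    estimates of 3.23-3.33 for the same taxa are accommodated by setting
    `c` explicitly.
    """

    c: float = 3.4

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("clock constant must be positive")


def kimura2p(P: float, Q: float) -> float:
    """K2P distance from transition proportion P and transversion proportion Q.

    Raises :class:`SaturationError` outside the domain 1-2P-Q > 0, 1-2Q > 0.
    """
    if P < 0 or Q < 0 or P + Q > 1:
        raise ValueError(f"invalid proportions P={P}, Q={Q}")
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        raise SaturationError(f"K2P undefined for P={P}, Q={Q}")
    return -0.5 * math.log(a * math.sqrt(b))


def copy_divergence(copy: str, consensus: str) -> DivergenceEstimate:
    """Count P and Q between an (ungapped-aligned) copy and its consensus.

    Sites where either sequence is not A/C/G/T are excluded from the
    comparison.  Raises ``ValueError`` when no sites are comparable and
    :class:`SaturationError` when the distance is undefined.
    """
    if len(copy) != len(consensus):
        raise ValueError("copy and consensus must be aligned to equal length")
    a = encode(copy)
    b = encode(consensus)
    comparable = (a < 4) & (b < 4)
    n = int(comparable.sum())
    if n == 0:
        raise ValueError("no comparable sites")
    diff = comparable & (a != b)
    ts = int((is_transition(a, b) & comparable).sum())
    tv = int(diff.sum()) - ts
    P = ts / n
    Q = tv / n
    return DivergenceEstimate(P=P, Q=Q, K=kimura2p(P, Q), sites_compared=n)


def time_axis(K, clock: ClockParams = ClockParams()):
    """Convert a K2P distance (scalar or array) to an age in mya.

    age = (K / 0.01) * c; linear and invertible.
    """
    if np.any(np.asarray(K) < 0):
        raise ValueError("K must be non-negative")
    if isinstance(K, np.ndarray):
        return (K / 0.01) * clock.c
    return (float(K) / 0.01) * clock.c


def build_landscape(
    copies: Iterable[tuple[str, int, float]],
    genome_length: int,
    bin_width: float = 0.01,
    clock: ClockParams = ClockParams(),
) -> pd.DataFrame:
    """Bin TE copies by divergence into a landscape table.

    Parameters
    ----------
    copies
        Iterables of ``(group, length_bases, K)``: the grouping label (TE
        class or superfamily), the copy's genomic footprint in bases, and
        its K2P divergence.
    genome_length
        Total genome size used to normalize fractions.
    bin_width
        Width of the substitution-ratio bins (0.01 matches the usual
        landscape resolution).

    Returns
    -------
    Long-format frame with columns ``group, bin_low, bin_high, fraction,
    age_mya`` (age of the bin's lower edge under the clock).  Each copy
    contributes its whole length to the single bin containing its K.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    acc: dict[tuple[str, int], float] = {}
    for group, length, K in copies:
        if K < 0:
            raise ValueError("divergence must be non-negative")
        k_bin = int(K / bin_width)
        acc[(group, k_bin)] = acc.get((group, k_bin), 0.0) + length
    rows = [
        {
            "group": g,
            "bin_low": b * bin_width,
            "bin_high": (b + 1) * bin_width,
            "fraction": bases / genome_length,
            "age_mya": time_axis(b * bin_width, clock),
        }
        for (g, b), bases in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows, columns=["group", "bin_low", "bin_high", "fraction", "age_mya"]
    )


def landscape_from_annotations(
    annotations: Sequence, genome_length: int, group_by: str = "class",
    bin_width: float = 0.01, clock: ClockParams = ClockParams(),
) -> pd.DataFrame:
    """Landscape from :class:`~pirnascape.composition.RepeatAnnotation` rows.

    ``group_by`` is ``"class"`` (DNA transposon vs retrotransposon etc.) or
    ``"superfamily"``.  Annotations without a divergence are skipped.
    """
    if group_by not in ("class", "superfamily"):
        raise ValueError("group_by must be 'class' or 'superfamily'")
    copies = []
    for ann in annotations:
        if ann.divergence is None:
            continue
        group = ann.repeat_class if group_by == "class" else ann.superfamily
        copies.append((group, ann.end - ann.start, ann.divergence))
    return build_landscape(copies, genome_length, bin_width=bin_width, clock=clock)


def modal_bin(landscape: pd.DataFrame, group: str) -> tuple[float, float]:
    """The (bin_low, bin_high) of the highest-fraction bin of one group."""
    sub = landscape[landscape["group"] == group]
    if sub.empty:
        raise ValueError(f"no bins for group {group!r}")
    row = sub.loc[sub["fraction"].idxmax()]
    return float(row["bin_low"]), float(row["bin_high"])
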