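"""VAF-based clonality, copy-number segment handling, and gain-allele placement.

Clonality bins partition tumor VAF in [0, 1]:

* ``subclonal`` — VAF ≤ 0.25: at the purity of a microdissected sample
  (~0.88), a heterozygous clonal mutation is expected near 0.44, so such low
  fractions indicate a subpopulation;
* ``intermediate`` — 0.25 < VAF < 0.35;
* ``clonal`` — 0.35 ≤ VAF < 0.70: consistent with a heterozygous mutation in
  (nearly) all tumor cells. The lower bound is inclusive at 0.35 (a printed
  "minor allele call of >35 %" only reproduces the published 9/25 count when
  the two 0.35 entries are counted in);
* ``homozygous_like`` — VAF ≥ 0.70: features of homozygosity.

For a single-copy gain (total copy number 3 in a pure tumor), a heterozygous
mutation sits either on the non-duplicated allele (expected VAF 1/3) or the
duplicated allele (expected VAF 2/3). ``gain_allele_placement`` weighs the
two with a binomial likelihood ratio, which reduces analytically to
``2**(n − 2k)`` in the pure-tumor case.

Copy-number segments use 1-based, fully closed coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import binom

from .variant_io import as_observation

__all__ = [
    "SEGMENT_STATES",
    "CnaSegment",
    "ClonalityCall",
    "AllelePlacement",
    "classify_clonality",
    "filter_segments",
    "overlap_cna",
    "gain_allele_placement",
    "estimate_purity",
]

SEGMENT_STATES = frozenset({"gain", "loss", "neutral_loh"})


@dataclass(frozen=True)
class CnaSegment:
    """A chromosome interval with a copy-number state and SNP-marker support."""

    chrom: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    state: str
    n_markers: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} before start {self.start}")
        if self.n_markers < 1:
            raise ValueError(f"segment needs >= 1 marker, got {self.n_markers}")
        if self.state not in SEGMENT_STATES:
            raise ValueError(f"unknown segment state {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClonalityCall:
    label: str  # subclonal | intermediate | clonal | homozygous_like
    vaf: float


@dataclass(frozen=True)
class AllelePlacement:
    """Binomial placement of a mutation under a single-copy gain."""

    k: int  # variant-supporting reads
    n: int  # total reads
    lr: float  # likelihood ratio, non-duplicated vs duplicated allele
    call: str  # non_duplicated | duplicated | ambiguous


def classify_clonality(vaf: float) -> ClonalityCall:
    """Assign the clonality bin of a tumor VAF (see module docstring)."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf {vaf} outside [0, 1]")
    if vaf <= 0.25:
        label = "subclonal"
    elif vaf < 0.35:
        label = "intermediate"
    elif vaf < 0.70:
        label = "clonal"
    else:
        label = "homozygous_like"
    return ClonalityCall(label=label, vaf=vaf)


def filter_segments(
    segments: Sequence[CnaSegment],
    min_markers: int = 5,
    min_length: int = 100_000,
) -> list[CnaSegment]:
    """Keep segments supported by >= 5 SNP markers and spanning >= 100 kb."""
    return [s for s in segments if s.n_markers >= min_markers and s.length >= min_length]


def overlap_cna(
    variants: Sequence, segments: Sequence[CnaSegment]
) -> list[Optional[CnaSegment]]:
    """Annotate each variant with the segment containing it, or ``None``.

    A variant at position ``pos`` overlaps a segment iff it is on the same
    chromosome and ``start <= pos <= end`` (closed interval). Segments must
    be disjoint per chromosome (one copy-number state per locus per sample);
    overlapping segments raise ``ValueError``.
    """
    by_chrom: dict[str, list[CnaSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    trees: dict[str, IntervalTree] = {}
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, nxt in zip(segs, segs[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"overlapping segments on chromosome {chrom}: "
                    f"[{prev.start}, {prev.end}] and [{nxt.start}, {nxt.end}]"
                )
        tree = IntervalTree()
        for seg in segs:
            tree[seg.start : seg.end + 1] = seg  # closed -> half-open
        trees[chrom] = tree

    annotations: list[Optional[CnaSegment]] = []
    for v in variants:
        obs = as_observation(v)
        hits = trees[obs.chrom][obs.pos] if obs.chrom in trees else ()
        annotations.append(next(iter(hits)).data if hits else None)
    return annotations


def gain_allele_placement(
    k: int,
    n: int,
    purity: Optional[float] = None,
    ambiguity_band: float = math.e,
) -> AllelePlacement:
    """Place a mutation on the non-duplicated vs duplicated allele of a gain.

    Compares Binomial(k; n, p_non) against Binomial(k; n, p_dup) where the
    expected fractions are 1/3 and 2/3 for a pure tumor. With ``purity`` p
    given, the expected VAF of a multiplicity-m mutation in a total of
    2(1−p) + 3p copies is ``p·m / (2(1−p) + 3p)``; ``purity=None`` (or 1)
    gives the pure-tumor 1/3 vs 2/3 comparison, for which the ratio equals
    ``2**(n − 2k)`` exactly.

    The call is ``ambiguous`` when the ratio lies inside
    ``[1/ambiguity_band, ambiguity_band]``, ``non_duplicated`` above it, and
    ``duplicated`` below.
    """
    if n <= 0:
        raise ValueError("total read count n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"variant reads k={k} outside [0, n={n}]")
    if ambiguity_band < 1:
        raise ValueError("ambiguity_band must be >= 1")
    if purity is None:
        p_non, p_dup = 1.0 / 3.0, 2.0 / 3.0
    else:
        if not 0.0 < purity <= 1.0:
            raise ValueError(f"purity {purity} outside (0, 1]")
        copies = 2.0 * (1.0 - purity) + 3.0 * purity
        p_non = purity / copies
        p_dup = 2.0 * purity / copies
    lr = float(np.exp(binom.logpmf(k, n, p_non) - binom.logpmf(k, n, p_dup)))
    if 1.0 / ambiguity_band <= lr <= ambiguity_band:
        call = "ambiguous"
    elif lr > ambiguity_band:
        call = "non_duplicated"
    else:
        call = "duplicated"
    return AllelePlacement(k=k, n=n, lr=lr, call=call)


def estimate_purity(clonal_vafs: Sequence[float]) -> float:
    """Tumor-purity estimate from clonal heterozygous VAFs: 2 × median VAF.

    A clonal heterozygous mutation on a diploid locus has expected VAF
    purity/2, so twice the median VAF of clonal calls estimates the tumor
    cell fraction. The estimate is not clipped; values slightly above 1 can
    occur by sampling noise and signal near-complete purity.
    """
    values = np.asarray(list(clonal_vafs), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one clonal VAF to estimate purity")
    return 2.0 * float(np.median(values))
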