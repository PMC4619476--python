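"""Shared constructors for unit tests."""

from __future__ import annotations

from somaticmz import PairedVariant, VariantObservation

_POS = [0]


def make_obs(
    chrom: str = "1",
    pos: int | None = None,
    ref: str = "A",
    alt: str = "G",
    depth: int = 50,
    vaf: float = 0.4,
    quality: float = 25.0,
    consequence: str = "missense",
    case_id: str = "case1",
    **kwargs,
) -> VariantObservation:
    if pos is None:
        _POS[0] += 1
        pos = 1000 + _POS[0]
    return VariantObservation(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        depth=depth,
        vaf=vaf,
        quality=quality,
        consequence=consequence,
        case_id=case_id,
        **kwargs,
    )


def make_pair(
    tumor_depth: int = 50,
    tumor_vaf: float = 0.4,
    normal_depth: int = 50,
    normal_vaf: float = 0.0,
    quality: float = 25.0,
    consequence: str = "missense",
    case_id: str = "case1",
    chrom: str = "1",
    pos: int | None = None,
    ref: str = "A",
    alt: str = "G",
) -> PairedVariant:
    tumor = make_obs(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        depth=tumor_depth,
        vaf=tumor_vaf,
        quality=quality,
        consequence=consequence,
        case_id=case_id,
    )
    normal = VariantObservation(
        chrom=tumor.chrom,
        pos=tumor.pos,
        ref=ref,
        alt=alt,
        depth=normal_depth,
        vaf=normal_vaf,
        consequence=consequence,
        case_id=case_id,
    )
    return PairedVariant(tumor=tumor, normal=normal, case_id=case_id)
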