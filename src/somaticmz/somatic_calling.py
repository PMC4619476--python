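"""The somatic filtering cascade: from raw non-synonymous calls to somatic SNVs.

Stages, applied in order:

1. **consequence** — drop calls whose consequence class is in
   ``FilterConfig.drop_consequences`` (by default intronic, UTR and
   synonymous; splice-site calls are retained even when the codon is
   unchanged);
2. **quality** — drop calls whose novel-allele quality falls below
   ``mean − k·sd`` of the qualities in the same calling (computed per
   case/sample, sample standard deviation with n−1 denominator);
3. **somatic rules** — require tumor depth ≥ 20, tumor VAF ≥ 0.1, normal VAF
   < 0.2 (strict) and tumor-minus-normal VAF delta ≥ 0.1, evaluated in that
   order so the rejection reason is the first failing rule;
4. **polymorphism** — drop exact (chrom, pos, ref, alt) matches against a
   known-polymorphism blacklist.

The quality threshold is data-dependent (recomputed from whatever enters the
stage), so the stage is a single pass, as the source pipeline applies it.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .variant_io import (
    FilterConfig,
    PairedVariant,
    VariantObservation,
    as_observation,
    variant_key,
)

__all__ = [
    "SomaticDecision",
    "CascadeReport",
    "quality_threshold",
    "filter_by_quality",
    "filter_consequence",
    "call_somatic",
    "filter_polymorphisms",
    "run_cascade",
    "load_blacklist",
]

logger = logging.getLogger(__name__)

Variant = Union[PairedVariant, VariantObservation]

REJECT_COVERAGE = "coverage"
REJECT_TUMOR_VAF = "tumor_vaf"
REJECT_NORMAL_VAF = "normal_vaf"
REJECT_DELTA = "delta"

STAGES = ("consequence", "quality", "somatic_rules", "polymorphism")


@dataclass(frozen=True)
class SomaticDecision:
    """Outcome of the paired somatic rules for one variant."""

    somatic: bool
    reason: Optional[str] = None  # first failing rule, None when somatic


@dataclass
class CascadeReport:
    """Per-stage attrition of the filtering cascade."""

    n_input: int
    n_after_consequence: int
    n_after_quality: int
    n_after_somatic_rules: int
    n_after_polymorphism: int
    removed: dict[str, list[tuple[Variant, str]]] = field(default_factory=dict)

    @property
    def total_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def to_dict(self) -> dict:
        """JSON-friendly summary: stage counts plus removal-reason tallies."""
        reasons: dict[str, dict[str, int]] = {}
        for stage, entries in self.removed.items():
            tally: dict[str, int] = {}
            for _, reason in entries:
                tally[reason] = tally.get(reason, 0) + 1
            reasons[stage] = tally
        return {
            "n_input": self.n_input,
            "n_after_consequence": self.n_after_consequence,
            "n_after_quality": self.n_after_quality,
            "n_after_somatic_rules": self.n_after_somatic_rules,
            "n_after_polymorphism": self.n_after_polymorphism,
            "removal_reasons": reasons,
        }


def quality_threshold(
    qualities: Sequence[float], sd_multiplier: float = 2.0
) -> float:
    """``mean − sd_multiplier · sd`` of a calling's novel-allele qualities.

    The standard deviation is the sample sd (n−1 denominator); a
    single-element list has sd 0, so the threshold equals that value.
    """
    values = np.asarray(list(qualities), dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute a quality threshold from an empty list")
    sd = 0.0 if values.size == 1 else float(values.std(ddof=1))
    return float(values.mean()) - sd_multiplier * sd


def _quality(variant: Variant) -> float:
    obs = as_observation(variant)
    if obs.quality is None:
        raise ValueError(f"variant at {variant_key(variant)} carries no quality")
    return obs.quality


def _case(variant: Variant) -> str:
    if isinstance(variant, PairedVariant):
        return variant.case_id
    return variant.case_id or ""


def filter_by_quality(
    variants: Sequence[Variant], cfg: FilterConfig = FilterConfig()
) -> tuple[list[Variant], list[tuple[Variant, str]]]:
    """Drop variants below the per-case quality threshold.

    The threshold adapts to each calling's quality distribution, so it is
    computed separately per case/sample rather than globally.
    """
    by_case: dict[str, list[float]] = defaultdict(list)
    for v in variants:
        by_case[_case(v)].append(_quality(v))
    thresholds = {
        case: quality_threshold(quals, cfg.quality_sd_multiplier)
        for case, quals in by_case.items()
    }
    kept: list[Variant] = []
    removed: list[tuple[Variant, str]] = []
    for v in variants:
        t = thresholds[_case(v)]
        if _quality(v) >= t:
            kept.append(v)
        else:
            removed.append((v, f"quality<{t:.3f}"))
    return kept, removed


def filter_consequence(
    variants: Sequence[Variant], cfg: FilterConfig = FilterConfig()
) -> tuple[list[Variant], list[tuple[Variant, str]]]:
    """Remove variants whose consequence class is in ``cfg.drop_consequences``."""
    kept: list[Variant] = []
    removed: list[tuple[Variant, str]] = []
    for v in variants:
        consequence = as_observation(v).consequence
        if consequence in cfg.drop_consequences:
            removed.append((v, f"consequence:{consequence}"))
        else:
            kept.append(v)
    return kept, removed


def call_somatic(pv: PairedVariant, cfg: FilterConfig = FilterConfig()) -> SomaticDecision:
    """Apply the paired tumor/normal somatic rules to one variant.

    A missing normal observation is treated as normal VAF = 0 (logged
    assumption) rather than an error: the variant simply cannot be explained
    by the control sample.
    """
    tumor = pv.tumor
    if pv.normal is None:
        logger.warning(
            "no normal observation at %s:%d %s>%s; assuming normal VAF = 0",
            tumor.chrom,
            tumor.pos,
            tumor.ref,
            tumor.alt,
        )
        normal_vaf = 0.0
    else:
        normal_vaf = pv.normal.vaf
    if tumor.depth < cfg.min_coverage:
        return SomaticDecision(False, REJECT_COVERAGE)
    if tumor.vaf < cfg.min_tumor_vaf:
        return SomaticDecision(False, REJECT_TUMOR_VAF)
    if normal_vaf >= cfg.max_normal_vaf:
        return SomaticDecision(False, REJECT_NORMAL_VAF)
    if tumor.vaf - normal_vaf < cfg.min_delta:
        return SomaticDecision(False, REJECT_DELTA)
    return SomaticDecision(True)


def filter_polymorphisms(
    variants: Sequence[Variant], blacklist: Iterable[tuple[str, int, str, str]]
) -> tuple[list[Variant], list[tuple[Variant, str]]]:
    """Exact-match removal of known polymorphisms on (chrom, pos, ref, alt)."""
    keys = frozenset(blacklist)
    kept: list[Variant] = []
    removed: list[tuple[Variant, str]] = []
    for v in variants:
        if variant_key(v) in keys:
            removed.append((v, "known_polymorphism"))
        else:
            kept.append(v)
    return kept, removed


def run_cascade(
    paired_variants: Sequence[PairedVariant],
    cfg: FilterConfig = FilterConfig(),
    blacklist: Iterable[tuple[str, int, str, str]] = frozenset(),
) -> tuple[list[PairedVariant], CascadeReport]:
    """Run the full cascade (consequence → quality → somatic rules → polymorphism).

    Deterministic for fixed input order; returns the somatic call set and a
    :class:`CascadeReport` with per-stage counts and per-variant removal
    reasons. The stage counts are non-increasing and
    ``n_input == len(somatic_set) + total removed``.
    """
    variants: list[PairedVariant] = list(paired_variants)
    removed: dict[str, list[tuple[Variant, str]]] = {stage: [] for stage in STAGES}
    n_input = len(variants)

    variants, removed["consequence"] = filter_consequence(variants, cfg)
    n_consequence = len(variants)

    if variants:
        variants, removed["quality"] = filter_by_quality(variants, cfg)
    n_quality = len(variants)

    kept_rules: list[PairedVariant] = []
    for pv in variants:
        decision = call_somatic(pv, cfg)
        if decision.somatic:
            kept_rules.append(pv)
        else:
            removed["somatic_rules"].append((pv, decision.reason or "rejected"))
    variants = kept_rules
    n_rules = len(variants)

    variants, removed["polymorphism"] = filter_polymorphisms(variants, blacklist)

    report = CascadeReport(
        n_input=n_input,
        n_after_consequence=n_consequence,
        n_after_quality=n_quality,
        n_after_somatic_rules=n_rules,
        n_after_polymorphism=len(variants),
        removed=removed,
    )
    return variants, report


def load_blacklist(path: str) -> frozenset[tuple[str, int, str, str]]:
    """Load a known-polymorphism locus list from a TSV with chrom/pos/ref/alt."""
    frame = pd.read_csv(str(path), sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "ref", "alt"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: blacklist missing columns {sorted(missing)}")
    return frozenset(
        (str(r.chrom), int(r.pos), str(r.ref).upper(), str(r.alt).upper())
        for r in frame.itertuples(index=False)
    )
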