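"""Classification and summarization of a somatic SNV call set.

Covers substitution type (transition vs transversion), mutation-class and
per-case tallies, and counts of the SIFT / PolyPhen-2 categories carried on
the input annotations (the categories are consumed, never computed).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .numerics import round_half_up
from .variant_io import (
    POLYPHEN_CATEGORIES,
    SIFT_CATEGORIES,
    ValidationError,
    as_observation,
)

__all__ = [
    "TRANSITION",
    "TRANSVERSION",
    "MutationSummary",
    "classify_substitution",
    "tally_predictions",
    "summarize_callset",
]

TRANSITION = "transition"
TRANSVERSION = "transversion"

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def classify_substitution(ref: str, alt: str) -> str:
    """Transition (purine↔purine or pyrimidine↔pyrimidine) vs transversion.

    The classification is symmetric in (ref, alt) and invariant under strand
    complement, so cDNA-strand alleles classify identically to genomic ones.
    """
    ref, alt = ref.upper(), alt.upper()
    bases = _PURINES | _PYRIMIDINES
    if ref not in bases or alt not in bases:
        raise ValueError(f"alleles must be single bases in ACGT, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref}); not a substitution")
    if (ref in _PURINES) == (alt in _PURINES):
        return TRANSITION
    return TRANSVERSION


def tally_predictions(variants: Sequence) -> tuple[dict[str, int], dict[str, int]]:
    """Exact counts of SIFT and PolyPhen-2 categories over a call set.

    ``not_applicable`` is counted separately (it is information: the
    predictor could not score the change, e.g. for truncating variants).
    Unknown category strings raise :class:`ValidationError`.
    """
    sift_counts: Counter[str] = Counter()
    polyphen_counts: Counter[str] = Counter()
    for v in variants:
        obs = as_observation(v)
        if obs.sift not in SIFT_CATEGORIES:
            raise ValidationError(f"unknown SIFT category {obs.sift!r}")
        if obs.polyphen not in POLYPHEN_CATEGORIES:
            raise ValidationError(f"unknown PolyPhen category {obs.polyphen!r}")
        sift_counts[obs.sift] += 1
        polyphen_counts[obs.polyphen] += 1
    return dict(sift_counts), dict(polyphen_counts)


@dataclass
class MutationSummary:
    """Order-independent summary of a somatic call set.

    Percentages are stored unrounded; use :meth:`display` for the half-up
    integer rounding used in printed summaries. For a pure substitution call
    set ``ti_count + tv_count == n_total`` and ``ti_pct + tv_pct == 100``.
    """

    n_total: int
    per_case: dict[str, int]
    class_counts: dict[str, int]
    ti_count: int
    tv_count: int
    ti_pct: float
    tv_pct: float
    sift_counts: dict[str, int] = field(default_factory=dict)
    polyphen_counts: dict[str, int] = field(default_factory=dict)

    def display(self) -> dict:
        return {
            "n_total": self.n_total,
            "per_case": dict(sorted(self.per_case.items())),
            "class_counts": dict(sorted(self.class_counts.items())),
            "ti_pct": round_half_up(self.ti_pct),
            "tv_pct": round_half_up(self.tv_pct),
            "sift_counts": dict(sorted(self.sift_counts.items())),
            "polyphen_counts": dict(sorted(self.polyphen_counts.items())),
        }


def summarize_callset(variants: Sequence) -> MutationSummary:
    """Summarize a somatic call set: classes, per-case counts, Ti/Tv, predictions.

    Splice-site variants with unchanged codons count as ``splice_site`` only
    (no double counting with synonymous). Deterministic and independent of
    input order.
    """
    observations = [as_observation(v) for v in variants]
    n_total = len(observations)
    per_case: Counter[str] = Counter()
    class_counts: Counter[str] = Counter()
    ti = 0
    for obs in observations:
        per_case[obs.case_id or ""] += 1
        class_counts[obs.consequence] += 1
        if classify_substitution(obs.ref, obs.alt) == TRANSITION:
            ti += 1
    tv = n_total - ti
    sift_counts, polyphen_counts = tally_predictions(observations)
    return MutationSummary(
        n_total=n_total,
        per_case=dict(per_case),
        class_counts=dict(class_counts),
        ti_count=ti,
        tv_count=tv,
        ti_pct=100.0 * ti / n_total if n_total else 0.0,
        tv_pct=100.0 * tv / n_total if n_total else 0.0,
        sift_counts=sift_counts,
        polyphen_counts=polyphen_counts,
    )
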