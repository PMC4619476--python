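"""Recurrence statistics across discovery and targeted-validation cohorts.

Per-site mutation frequencies are simple binomial proportions; arms can be
pooled when the discovery and validation samples are treated as exchangeable
draws from the same patient population. Exact (Clopper–Pearson) confidence
intervals quantify the uncertainty the small screens carry.

Display rounding follows reporting practice: one decimal for per-arm
frequencies (e.g. 12.5 %), integer percent for pooled headline numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .numerics import round_half_up

__all__ = [
    "RecurrenceRecord",
    "arm_frequency",
    "pooled_frequency",
    "exact_ci",
    "load_cohort_table",
]

VALID_STATUSES = frozenset({"mutated", "wildtype", "failed"})


@dataclass
class RecurrenceRecord:
    """Per-site mutated/screened counts in the discovery and validation arms."""

    site: str
    n_mutated_discovery: int
    n_discovery: int
    n_mutated_validation: int
    n_validation: int

    def __post_init__(self) -> None:
        for mutated, screened, arm in (
            (self.n_mutated_discovery, self.n_discovery, "discovery"),
            (self.n_mutated_validation, self.n_validation, "validation"),
        ):
            if not 0 <= mutated <= screened:
                raise ValueError(
                    f"{self.site}: {arm} arm has mutated={mutated} outside "
                    f"[0, screened={screened}]"
                )


def arm_frequency(
    mutated: int, screened: int, ndigits: Optional[int] = 1
) -> float:
    """Percentage of mutated samples in one arm, rounded half-up to one decimal.

    Pass ``ndigits=None`` for the unrounded value.
    """
    if screened <= 0:
        raise ValueError("screened must be positive")
    if not 0 <= mutated <= screened:
        raise ValueError(f"mutated={mutated} outside [0, screened={screened}]")
    pct = 100.0 * mutated / screened
    return pct if ndigits is None else round_half_up(pct, ndigits)


def pooled_frequency(rec: RecurrenceRecord, ndigits: Optional[int] = 0) -> float:
    """Pooled percentage across both arms, rounded half-up to integer percent.

    Pools counts, not arm percentages, so the value is the sample-size
    weighted mean of the two arm frequencies. Pass ``ndigits=None`` for the
    unrounded value.
    """
    screened = rec.n_discovery + rec.n_validation
    if screened == 0:
        raise ValueError(f"{rec.site}: both arms empty")
    mutated = rec.n_mutated_discovery + rec.n_mutated_validation
    pct = 100.0 * mutated / screened
    return pct if ndigits is None else round_half_up(pct, ndigits)


def exact_ci(
    mutated: int, screened: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper–Pearson exact confidence interval for a proportion, in percent."""
    if screened <= 0:
        raise ValueError("screened must be positive")
    if not 0 <= mutated <= screened:
        raise ValueError(f"mutated={mutated} outside [0, screened={screened}]")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level {level} outside (0, 1)")
    lo, hi = proportion_confint(mutated, screened, alpha=1.0 - level, method="beta")
    lo = 0.0 if np.isnan(lo) else float(lo)
    hi = 1.0 if np.isnan(hi) else float(hi)
    return 100.0 * lo, 100.0 * hi


def load_cohort_table(path: str) -> tuple[dict[str, RecurrenceRecord], int]:
    """Aggregate a per-sample genotyping table into per-site recurrence records.

    Expects a TSV with columns ``site``, ``sample_id``, ``arm``
    ({discovery, validation}) and ``status`` ({mutated, wildtype, failed}).
    ``failed`` assays are excluded from denominators; their count is returned
    alongside the records.
    """
    frame = pd.read_csv(str(path), sep="\t", dtype=str)
    missing = {"site", "sample_id", "arm", "status"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: cohort table missing columns {sorted(missing)}")
    bad_status = set(frame["status"]) - VALID_STATUSES
    if bad_status:
        raise ValueError(f"{path}: unknown status values {sorted(bad_status)}")
    bad_arm = set(frame["arm"]) - {"discovery", "validation"}
    if bad_arm:
        raise ValueError(f"{path}: unknown arm values {sorted(bad_arm)}")

    n_failed = int((frame["status"] == "failed").sum())
    usable = frame[frame["status"] != "failed"]
    records: dict[str, RecurrenceRecord] = {}
    for site, group in usable.groupby("site", sort=True):
        disc = group[group["arm"] == "discovery"]
        val = group[group["arm"] == "validation"]
        records[str(site)] = RecurrenceRecord(
            site=str(site),
            n_mutated_discovery=int((disc["status"] == "mutated").sum()),
            n_discovery=len(disc),
            n_mutated_validation=int((val["status"] == "mutated").sum()),
            n_validation=len(val),
        )
    return records, n_failed
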