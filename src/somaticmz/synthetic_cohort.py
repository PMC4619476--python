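"""Synthetic paired tumor/normal cohorts with known ground truth.

The generator emulates the statistical structure of a microdissected
tumor/normal exome pair at the study's operating point — tumor purity ~0.88,
mean sequencing depth 47× — using binomial read sampling at each locus:

* **germline heterozygous SNPs** — expected allele fraction 0.5 in both
  tissues: alt reads ~ Binomial(depth, 0.5) independently in tumor and
  normal;
* **somatic variants** — tumor alt reads ~ Binomial(depth, purity·CCF/2) on
  diploid loci (CCF drawn from a configurable clonal/subclonal mixture),
  normal alt reads ~ Binomial(depth, error_rate). Inside a simulated
  copy-number gain the success fraction becomes
  purity·CCF·m / (2(1−purity) + 3·purity) for allele multiplicity m;
* **sequencing-error artifacts** — tumor-only noise,
  alt reads ~ Binomial(depth, error_rate);
* **known polymorphisms** — germline hets at database-known sites; the
  matched normal suffers allele dropout with a configurable rate, so a
  fraction of them masquerade as somatic and must be caught by the
  blacklist stage.

Per-locus depths come from a Poisson (default) or negative-binomial model.
Novel-allele qualities for true variants are uniform over the observed
calling-quality range (17–32); artifact qualities are uniform over a lower
band (8–20), so the data-driven mean − 2·sd quality filter clips artifacts
but not true variants. Everything is reproducible from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clonality_cna import CnaSegment
from .variant_io import (
    INTRONIC,
    MISSENSE,
    NONSENSE,
    SPLICE_SITE,
    SYNONYMOUS,
    UTR,
    PairedVariant,
    VariantObservation,
    variant_key,
)

__all__ = [
    "SimulationConfig",
    "TruthLabel",
    "simulate_pair",
    "simulate_cna_profile",
    "simulate_validation_cohort",
    "blacklist_from_truth",
]

GERMLINE = "germline"
SOMATIC = "somatic"
ARTIFACT = "artifact"
POLYMORPHISM = "polymorphism"

_BASES = np.array(list("ACGT"))

# Consequence mixtures per origin. Somatic weights mirror the discovery call
# set (23 missense / 1 nonsense / 1 splice site); germline calls include the
# synonymous/intronic/UTR classes the consequence filter exists to remove.
_SOMATIC_CSQ = ([MISSENSE, NONSENSE, SPLICE_SITE], [0.92, 0.04, 0.04])
_GERMLINE_CSQ = (
    [MISSENSE, SYNONYMOUS, INTRONIC, UTR],
    [0.30, 0.25, 0.35, 0.10],
)
_ARTIFACT_CSQ = ([MISSENSE, SYNONYMOUS, INTRONIC, UTR], [0.50, 0.20, 0.20, 0.10])
_POLYMORPHISM_CSQ = ([MISSENSE, SYNONYMOUS], [0.80, 0.20])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated tumor/normal exome pair.

    Defaults encode the discovery setting: purity 0.88 (microdissection
    yields 87–89 % tumor cells), mean depth 47×, a CCF mixture with half of
    the somatic burden clonal, and a 10^-3 per-base error rate.
    """

    purity: float = 0.88
    mean_depth: float = 47.0
    depth_model: str = "poisson"  # or "negative_binomial"
    depth_dispersion: float = 8.0  # nbinom size parameter; var = mu + mu^2/size
    n_germline_het: int = 1000
    n_somatic: int = 25
    n_artifacts: int = 50
    n_polymorphisms: int = 100
    ccf_distribution: tuple[tuple[float, float], ...] = (
        (1.0, 0.5),
        (0.5, 0.3),
        (0.25, 0.2),
    )
    error_rate: float = 0.001
    polymorphism_dropout: float = 0.5
    variant_quality_range: tuple[float, float] = (17.0, 32.0)
    artifact_quality_range: tuple[float, float] = (8.0, 20.0)
    case_id: str = "sim1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity {self.purity} outside (0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_model not in {"poisson", "negative_binomial"}:
            raise ValueError(f"unknown depth model {self.depth_model!r}")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        for name in ("n_germline_het", "n_somatic", "n_artifacts", "n_polymorphisms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        weights = [w for _, w in self.ccf_distribution]
        if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
            raise ValueError("ccf_distribution weights must be non-negative and sum to 1")
        if any(not 0.0 < c <= 1.0 for c, _ in self.ccf_distribution):
            raise ValueError("ccf values must lie in (0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate {self.error_rate} outside [0, 1)")
        if not 0.0 <= self.polymorphism_dropout <= 1.0:
            raise ValueError("polymorphism_dropout outside [0, 1]")
        for lo, hi in (self.variant_quality_range, self.artifact_quality_range):
            if not 0 <= lo <= hi:
                raise ValueError("quality ranges must satisfy 0 <= lo <= hi")


@dataclass(frozen=True)
class TruthLabel:
    """Ground-truth bookkeeping for one simulated locus."""

    origin: str  # germline | somatic | artifact | polymorphism
    ccf: Optional[float] = None  # somatic entries carry their cancer cell fraction
    on_duplicated_allele: Optional[bool] = None  # somatic entries inside a gain

    def __post_init__(self) -> None:
        if self.origin == SOMATIC and self.ccf is None:
            raise ValueError("somatic truth labels must carry a CCF")


def _depths(rng: np.random.Generator, cfg: SimulationConfig, size: int) -> np.ndarray:
    if cfg.depth_model == "poisson":
        d = rng.poisson(cfg.mean_depth, size=size)
    else:
        size_param = cfg.depth_dispersion
        p = size_param / (size_param + cfg.mean_depth)
        d = rng.negative_binomial(size_param, p, size=size)
    return np.maximum(d, 1)


def _alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def _consequence(rng: np.random.Generator, mixture) -> str:
    classes, probs = mixture
    return str(rng.choice(classes, p=probs))


def _make_pair(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    index: int,
    origin: str,
    p_tumor: float,
    p_normal: float,
    mixture,
    chrom: Optional[str] = None,
    pos: Optional[int] = None,
) -> PairedVariant:
    if chrom is None:
        chrom = str(rng.integers(1, 23))
    if pos is None:
        pos = int(rng.integers(1, 150_000_000))
    ref, alt = _alleles(rng)
    dt, dn = (int(x) for x in _depths(rng, cfg, 2))
    t_alt = int(rng.binomial(dt, p_tumor))
    n_alt = int(rng.binomial(dn, p_normal))
    q_lo, q_hi = (
        cfg.artifact_quality_range if origin == ARTIFACT else cfg.variant_quality_range
    )
    quality = float(rng.uniform(q_lo, q_hi))
    consequence = _consequence(rng, mixture)
    gene = f"GENE{index:05d}"
    tumor = VariantObservation(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        depth=dt,
        alt_reads=t_alt,
        vaf=t_alt / dt,
        quality=quality,
        consequence=consequence,
        gene=gene,
        case_id=cfg.case_id,
    )
    normal = VariantObservation(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        depth=dn,
        alt_reads=n_alt,
        vaf=n_alt / dn,
        quality=float(rng.uniform(*cfg.variant_quality_range)),
        consequence=consequence,
        gene=gene,
        case_id=cfg.case_id,
    )
    return PairedVariant(tumor=tumor, normal=normal, case_id=cfg.case_id)


def simulate_pair(
    cfg: SimulationConfig,
    segments: Optional[Sequence[CnaSegment]] = None,
    n_somatic_in_gain: int = 0,
) -> tuple[list[PairedVariant], list[TruthLabel]]:
    """Simulate one tumor/normal variant table with parallel truth labels.

    Returns ``(pairs, truth)`` with ``truth[i]`` describing ``pairs[i]``.
    When ``segments`` contains a gain and ``n_somatic_in_gain > 0``, that
    many clonal somatic variants are placed inside the first gain segment
    with allele multiplicity drawn fairly (on the duplicated allele with
    probability 1/2). The output order is shuffled but fully determined by
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    gain = None
    if segments is not None:
        gain = next((s for s in segments if s.state == "gain"), None)
    if n_somatic_in_gain > 0 and gain is None:
        raise ValueError("n_somatic_in_gain > 0 requires a gain segment")

    ccfs = [c for c, _ in cfg.ccf_distribution]
    ccf_weights = [w for _, w in cfg.ccf_distribution]
    diploid_copies = 2.0
    gain_copies = 2.0 * (1.0 - cfg.purity) + 3.0 * cfg.purity

    entries: list[tuple[PairedVariant, TruthLabel]] = []
    index = 0

    for _ in range(cfg.n_germline_het):
        pv = _make_pair(rng, cfg, index, GERMLINE, 0.5, 0.5, _GERMLINE_CSQ)
        entries.append((pv, TruthLabel(origin=GERMLINE)))
        index += 1

    for i in range(cfg.n_somatic):
        in_gain = i < n_somatic_in_gain
        if in_gain:
            ccf = 1.0
            on_dup = bool(rng.random() < 0.5)
            multiplicity = 2 if on_dup else 1
            p_t = cfg.purity * ccf * multiplicity / gain_copies
            chrom, pos = gain.chrom, int(rng.integers(gain.start, gain.end + 1))
        else:
            ccf = float(rng.choice(ccfs, p=ccf_weights))
            on_dup = None
            p_t = cfg.purity * ccf / diploid_copies
            chrom = pos = None
        pv = _make_pair(
            rng, cfg, index, SOMATIC, p_t, cfg.error_rate, _SOMATIC_CSQ, chrom, pos
        )
        entries.append((pv, TruthLabel(origin=SOMATIC, ccf=ccf, on_duplicated_allele=on_dup)))
        index += 1

    for _ in range(cfg.n_artifacts):
        pv = _make_pair(rng, cfg, index, ARTIFACT, cfg.error_rate, 0.0, _ARTIFACT_CSQ)
        entries.append((pv, TruthLabel(origin=ARTIFACT)))
        index += 1

    for _ in range(cfg.n_polymorphisms):
        dropout = rng.random() < cfg.polymorphism_dropout
        p_n = cfg.error_rate if dropout else 0.5
        pv = _make_pair(rng, cfg, index, POLYMORPHISM, 0.5, p_n, _POLYMORPHISM_CSQ)
        entries.append((pv, TruthLabel(origin=POLYMORPHISM)))
        index += 1

    order = rng.permutation(len(entries))
    pairs = [entries[i][0] for i in order]
    truth = [entries[i][1] for i in order]
    return pairs, truth


def blacklist_from_truth(
    pairs: Sequence[PairedVariant], truth: Sequence[TruthLabel]
) -> frozenset[tuple[str, int, str, str]]:
    """Known-polymorphism loci of a simulated pair, as a cascade blacklist."""
    return frozenset(
        variant_key(pv) for pv, t in zip(pairs, truth) if t.origin == POLYMORPHISM
    )


def simulate_cna_profile(
    cfg: Optional[SimulationConfig] = None, include_decoys: bool = False
) -> list[CnaSegment]:
    """Copy-number profile analog of the discovery cases: one 3q-like gain and
    one 7q-like loss, both comfortably above the 5-marker / 100-kb floor.

    With ``include_decoys=True`` two sub-threshold segments are added (one
    below the marker floor, one below the length floor) that
    :func:`somaticmz.clonality_cna.filter_segments` must drop. Marker counts
    assume roughly one array SNP per 7 kb.
    """
    del cfg  # coordinates are fixed analogs; kept for interface symmetry

    def markers(start: int, end: int) -> int:
        return (end - start + 1) // 7_000

    segments = [
        CnaSegment("3", 93_500_000, 197_800_000, "gain", markers(93_500_000, 197_800_000)),
        CnaSegment("7", 124_100_000, 158_900_000, "loss", markers(124_100_000, 158_900_000)),
    ]
    if include_decoys:
        segments.append(CnaSegment("3", 50_000_000, 50_049_999, "gain", 12))
        segments.append(CnaSegment("7", 30_000_000, 30_499_999, "loss", 4))
    return segments


def simulate_validation_cohort(
    site_prevalences: dict[str, float],
    n_samples: int,
    seed: int,
    failure_rate: float = 0.0,
    arm: str = "validation",
) -> pd.DataFrame:
    """Per-sample genotyping table for a targeted validation screen.

    Each sample's status at each site is an independent Bernoulli draw with
    the site's prevalence; assays fail independently at ``failure_rate`` and
    are recorded as ``failed`` (to be excluded from denominators downstream).
    """
    for site, prev in site_prevalences.items():
        if not 0.0 <= prev <= 1.0:
            raise ValueError(f"{site}: prevalence {prev} outside [0, 1]")
    if not 0.0 <= failure_rate < 1.0:
        raise ValueError(f"failure_rate {failure_rate} outside [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for site in sorted(site_prevalences):
        prev = site_prevalences[site]
        for i in range(n_samples):
            if failure_rate and rng.random() < failure_rate:
                status = "failed"
            else:
                status = "mutated" if rng.random() < prev else "wildtype"
            rows.append(
                {"site": site, "sample_id": f"S{i + 1:04d}", "arm": arm, "status": status}
            )
    return pd.DataFrame(rows, columns=["site", "sample_id", "arm", "status"])
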