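"""Domain types and I/O for paired tumor/normal single-nucleotide variant tables.

The package works on small per-variant call tables rather than raw reads: each
record is one called single-base substitution in one tissue, carrying read
depth, variant-supporting read count, variant allele fraction (VAF), the
caller's novel-allele quality, and functional annotation (a consequence class
plus SIFT / PolyPhen-2 categories, which are consumed as input and never
computed here).

Two on-disk dialects are supported:

* ``tsv`` — one row per paired observation, column names mirroring the
  discovery call-set layout (``tumor_depth``, ``tumor_vaf``, ... and the
  corresponding ``normal_*`` columns);
* ``vcf`` — VCF 4.2 with one sample column per tissue (``TUMOR`` and
  ``NORMAL``), depth in ``FORMAT/DP``, allelic depths in ``FORMAT/AD``,
  allele fraction in ``FORMAT/AF`` and novel-allele quality in ``FORMAT/NQ``.

Coordinates are 1-based and fully closed throughout, matching VCF convention.
Only single-nucleotide substitutions are modeled; indels and multi-base
changes are rejected at parse time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "CONSEQUENCES",
    "SIFT_CATEGORIES",
    "POLYPHEN_CATEGORIES",
    "HgvsParseError",
    "SchemaError",
    "ValidationError",
    "VariantObservation",
    "PairedVariant",
    "FilterConfig",
    "as_observation",
    "variant_key",
    "parse_cdna_change",
    "parse_protein_change",
    "load_discovery_frame",
    "load_discovery_snvs",
    "pair_with_clean_normal",
    "load_variant_table",
    "write_variant_table",
]

# Consequence classes of a coding-region SNV. "splice_site" is kept distinct
# from "synonymous" because a substitution in the last exonic base can leave
# the codon unchanged yet destroy the splice donor/acceptor.
MISSENSE = "missense"
NONSENSE = "nonsense"
SPLICE_SITE = "splice_site"
SYNONYMOUS = "synonymous"
INTRONIC = "intronic"
UTR = "utr"
OTHER = "other"

CONSEQUENCES = frozenset(
    {MISSENSE, NONSENSE, SPLICE_SITE, SYNONYMOUS, INTRONIC, UTR, OTHER}
)
SIFT_CATEGORIES = frozenset({"damaging", "tolerated", "stop_gained", "not_applicable"})
POLYPHEN_CATEGORIES = frozenset(
    {"benign", "possibly_damaging", "probably_damaging", "not_applicable"}
)

# Printed VAFs are rounded to two decimals, so alt_reads/depth may differ from
# the stored fraction by up to half a unit in the second decimal.
VAF_ROUNDING_TOL = 0.005

_BASES = frozenset("ACGT")
_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class HgvsParseError(ValueError):
    """A sequence-change string does not describe a single-base substitution."""


class SchemaError(ValueError):
    """A variant table is missing mandatory columns or fields."""


class ValidationError(ValueError):
    """A field value violates a domain invariant (e.g. VAF outside [0, 1])."""


@dataclass
class VariantObservation:
    """One called single-base substitution in one tissue sample.

    ``vaf`` is the fraction of reads supporting the variant allele; when
    ``alt_reads`` is present it must agree with ``alt_reads / depth`` to
    within :data:`VAF_ROUNDING_TOL`. ``quality`` is the caller's novel-allele
    mean quality, a dimensionless non-negative real.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    vaf: float
    alt_reads: Optional[int] = None
    quality: Optional[float] = None
    consequence: str = OTHER
    gene: str = ""
    cdna_change: Optional[str] = None
    protein_change: Optional[str] = None
    sift: str = "not_applicable"
    polyphen: str = "not_applicable"
    case_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: alleles must be single bases in ACGT, "
                f"got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"{self.chrom}:{self.pos}: ref equals alt ({self.ref})")
        if self.depth < 0:
            raise ValidationError(f"{self.chrom}:{self.pos}: negative depth {self.depth}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"{self.chrom}:{self.pos}: vaf {self.vaf} outside [0, 1]")
        if self.alt_reads is not None:
            if not 0 <= self.alt_reads <= self.depth:
                raise ValidationError(
                    f"{self.chrom}:{self.pos}: alt_reads {self.alt_reads} outside "
                    f"[0, depth={self.depth}]"
                )
            if self.depth > 0:
                implied = self.alt_reads / self.depth
                if abs(implied - self.vaf) > VAF_ROUNDING_TOL + 1e-12:
                    raise ValidationError(
                        f"{self.chrom}:{self.pos}: vaf {self.vaf} inconsistent with "
                        f"alt_reads/depth = {implied:.4f}"
                    )
        if self.quality is not None and self.quality < 0:
            raise ValidationError(f"{self.chrom}:{self.pos}: negative quality {self.quality}")
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence {self.consequence!r}")
        if self.sift not in SIFT_CATEGORIES:
            raise ValidationError(f"unknown SIFT category {self.sift!r}")
        if self.polyphen not in POLYPHEN_CATEGORIES:
            raise ValidationError(f"unknown PolyPhen category {self.polyphen!r}")
        # HGVS strings are stored whitespace-normalized (tables in the wild mix
        # spaced and unspaced spellings of the same change).
        if self.cdna_change is not None:
            self.cdna_change = "".join(self.cdna_change.split()) or None
        if self.protein_change is not None:
            self.protein_change = "".join(self.protein_change.split()) or None


@dataclass
class PairedVariant:
    """Tumor and matched-normal observations at one locus — the unit of somatic calling.

    ``normal`` may be ``None`` when the control sample has no usable
    observation at the site; downstream rules then treat the normal allele
    fraction as 0 (with a logged assumption).
    """

    tumor: VariantObservation
    normal: Optional[VariantObservation]
    case_id: str

    def __post_init__(self) -> None:
        if self.normal is not None:
            same_locus = (
                self.tumor.chrom == self.normal.chrom
                and self.tumor.pos == self.normal.pos
                and self.tumor.ref == self.normal.ref
                and self.tumor.alt == self.normal.alt
            )
            if not same_locus:
                raise ValidationError(
                    "tumor and normal observations disagree on locus/alleles: "
                    f"{variant_key(self.tumor)} vs {variant_key(self.normal)}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return variant_key(self.tumor)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the somatic filtering cascade.

    Defaults reproduce the discovery pipeline: coverage >= 20, tumor VAF >=
    0.1, normal VAF < 0.2 (strict), tumor-minus-normal VAF delta >= 0.1,
    quality cutoff at mean − 2·sd of the calling's novel-allele qualities, and
    removal of intronic/UTR/synonymous calls. All "minimum / at least"
    thresholds are inclusive; the normal-VAF cap is strict.
    """

    min_coverage: int = 20
    min_tumor_vaf: float = 0.1
    max_normal_vaf: float = 0.2
    min_delta: float = 0.1
    quality_sd_multiplier: float = 2.0
    drop_consequences: frozenset[str] = frozenset({SYNONYMOUS, INTRONIC, UTR})

    def __post_init__(self) -> None:
        for name in ("min_tumor_vaf", "max_normal_vaf", "min_delta"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name}={value} outside [0, 1]")
        if self.min_coverage < 0:
            raise ValidationError(f"min_coverage={self.min_coverage} must be >= 0")
        unknown = set(self.drop_consequences) - CONSEQUENCES
        if unknown:
            raise ValidationError(f"unknown consequences in drop set: {sorted(unknown)}")
        object.__setattr__(self, "drop_consequences", frozenset(self.drop_consequences))


def as_observation(variant: "PairedVariant | VariantObservation") -> VariantObservation:
    """Return the tumor observation of a pair, or the observation itself."""
    return variant.tumor if isinstance(variant, PairedVariant) else variant


def variant_key(variant: "PairedVariant | VariantObservation") -> tuple[str, int, str, str]:
    """(chrom, pos, ref, alt) identity of a variant, usable as a dict/set key."""
    obs = as_observation(variant)
    return (obs.chrom, obs.pos, obs.ref, obs.alt)


# ---------------------------------------------------------------------------
# HGVS-style change strings
# ---------------------------------------------------------------------------

_CDNA_RE = re.compile(r"^C\.(\d+)([ACGT])>([ACGT])$")
_PROTEIN_RE = re.compile(r"^P\.([A-Z])(\d+)([A-Z*]?)$")


def parse_cdna_change(s: str) -> tuple[int, str, str]:
    """Parse a cDNA substitution like ``c.794 T > C`` or ``c.8C>T``.

    Whitespace is normalized before matching, so spaced and unspaced
    spellings are both accepted. Returns ``(cdna_pos, ref, alt)`` with
    upper-cased bases.

    Raises :class:`HgvsParseError` for anything that is not a single-base
    substitution (deletions, insertions, multi-base changes, ...).
    """
    if not isinstance(s, str) or not s.strip():
        raise HgvsParseError(f"empty or non-string cDNA change: {s!r}")
    token = "".join(s.split()).upper()
    m = _CDNA_RE.match(token)
    if m is None:
        raise HgvsParseError(f"not a single-base cDNA substitution: {s!r}")
    return int(m.group(1)), m.group(2), m.group(3)


def parse_protein_change(
    s: str, splice_site: bool = False, stop_gained: bool = False
) -> str:
    """Classify a protein-level change string like ``p.L265P``.

    Rules:

    * alternate residue is ``*`` or the record is flagged ``stop_gained``
      → ``"nonsense"``;
    * reference residue equals alternate residue and the record is flagged as
      a splice-site change → ``"splice_site"`` (the codon is unchanged but
      splicing is disrupted);
    * reference equals alternate otherwise → ``"synonymous"``;
    * different residues → ``"missense"``.

    A change with no alternate residue (e.g. ``p.Q2364``) is only meaningful
    together with a stop-gained flag; otherwise it is a parse error.
    """
    if not isinstance(s, str) or not s.strip():
        raise HgvsParseError(f"empty or non-string protein change: {s!r}")
    token = "".join(s.split())
    m = _PROTEIN_RE.match(token.upper())
    if m is None:
        raise HgvsParseError(f"malformed protein change: {s!r}")
    ref_aa, _, alt_aa = m.groups()
    if ref_aa not in _AMINO_ACIDS:
        raise HgvsParseError(f"unknown reference residue in {s!r}")
    if alt_aa == "*" or stop_gained:
        return NONSENSE
    if alt_aa == "":
        raise HgvsParseError(f"missing alternate residue in {s!r}")
    if alt_aa not in _AMINO_ACIDS:
        raise HgvsParseError(f"unknown alternate residue in {s!r}")
    if alt_aa == ref_aa:
        return SPLICE_SITE if splice_site else SYNONYMOUS
    return MISSENSE


# ---------------------------------------------------------------------------
# Packaged discovery call set
# ---------------------------------------------------------------------------

_FIXTURE_NAME = "smzl_wes_discovery_snvs.tsv"

_SIFT_LABELS = {
    "Damaging": "damaging",
    "Tolerated": "tolerated",
    "Stop gained": "stop_gained",
    "N/A": "not_applicable",
}
_POLYPHEN_LABELS = {
    "Benign": "benign",
    "Possibly damaging": "possibly_damaging",
    "Probably damaging": "probably_damaging",
    "N/A": "not_applicable",
}


def load_discovery_frame() -> pd.DataFrame:
    """Raw packaged discovery call set (25 somatic SNVs from two SMZL exomes).

    Values are kept as printed in the source call table: HGVS strings retain
    their mixed spacing, prediction labels their display capitalization, and
    the ``footnote`` column carries the splice-site / stop-gained flags.
    """
    path = resources.files("somaticmz.data").joinpath(_FIXTURE_NAME)
    with path.open("r") as handle:
        return pd.read_csv(
            handle,
            sep="\t",
            dtype={"case": str, "chrom": str, "exon": "string"},
            keep_default_na=False,
        )


def load_discovery_snvs() -> list[VariantObservation]:
    """Typed view of the packaged discovery call set.

    Genomic ref/alt bases are taken from the cDNA substitution (transcript
    strand); this is immaterial for transition/transversion classification,
    which is complement-invariant. ``alt_reads`` is reconstructed as
    ``round(vaf * depth)``, consistent with the printed two-decimal VAFs.
    """
    frame = load_discovery_frame()
    records: list[VariantObservation] = []
    for row in frame.itertuples(index=False):
        _, ref, alt = parse_cdna_change(row.nucleotide_change)
        consequence = parse_protein_change(
            row.aa_change,
            splice_site=row.footnote == "splice site",
            stop_gained=row.footnote == "stop gained",
        )
        depth = int(row.coverage_tumor)
        vaf = float(row.snv_frequency)
        records.append(
            VariantObservation(
                chrom=str(row.chrom),
                pos=int(row.position),
                ref=ref,
                alt=alt,
                depth=depth,
                alt_reads=round(vaf * depth),
                vaf=vaf,
                quality=float(row.quality_score),
                consequence=consequence,
                gene=row.gene,
                cdna_change=row.nucleotide_change,
                protein_change=row.aa_change,
                sift=_SIFT_LABELS[row.sift_prediction],
                polyphen=_POLYPHEN_LABELS[row.polyphen2_prediction],
                case_id=str(row.case),
            )
        )
    return records


def pair_with_clean_normal(
    obs: VariantObservation, normal_depth: Optional[int] = None
) -> PairedVariant:
    """Wrap a tumor observation into a pair with a variant-free matched normal.

    Useful for running tumor-only call sets (such as the packaged discovery
    set, whose matched-normal read counts are not published) through the
    paired somatic rules.
    """
    depth = obs.depth if normal_depth is None else normal_depth
    normal = VariantObservation(
        chrom=obs.chrom,
        pos=obs.pos,
        ref=obs.ref,
        alt=obs.alt,
        depth=depth,
        alt_reads=0,
        vaf=0.0,
        consequence=obs.consequence,
        gene=obs.gene,
        case_id=obs.case_id,
    )
    return PairedVariant(tumor=obs, normal=normal, case_id=obs.case_id or "")


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TSV_MANDATORY = ["case_id", "chrom", "pos", "ref", "alt", "tumor_depth", "tumor_vaf"]
_TSV_COLUMNS = [
    "case_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "cdna_change",
    "protein_change",
    "sift",
    "polyphen",
    "tumor_depth",
    "tumor_alt_reads",
    "tumor_vaf",
    "tumor_quality",
    "normal_depth",
    "normal_alt_reads",
    "normal_vaf",
    "normal_quality",
]


def _opt(value):
    if value is None:
        return ""
    return value


def _opt_int(value) -> Optional[int]:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    return int(float(value))


def _opt_float(value) -> Optional[float]:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def pairs_to_frame(pairs: Iterable[PairedVariant]) -> pd.DataFrame:
    rows = []
    for pv in pairs:
        t, n = pv.tumor, pv.normal
        rows.append(
            {
                "case_id": pv.case_id,
                "chrom": t.chrom,
                "pos": t.pos,
                "ref": t.ref,
                "alt": t.alt,
                "gene": t.gene,
                "consequence": t.consequence,
                "cdna_change": _opt(t.cdna_change),
                "protein_change": _opt(t.protein_change),
                "sift": t.sift,
                "polyphen": t.polyphen,
                "tumor_depth": t.depth,
                "tumor_alt_reads": _opt(t.alt_reads),
                "tumor_vaf": t.vaf,
                "tumor_quality": _opt(t.quality),
                "normal_depth": _opt(n.depth if n else None),
                "normal_alt_reads": _opt(n.alt_reads if n else None),
                "normal_vaf": _opt(n.vaf if n else None),
                "normal_quality": _opt(n.quality if n else None),
            }
        )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def frame_to_pairs(frame: pd.DataFrame, source: str = "<memory>") -> list[PairedVariant]:
    missing = [c for c in _TSV_MANDATORY if c not in frame.columns]
    if missing:
        raise SchemaError(f"{source}: missing mandatory columns {missing}")
    pairs: list[PairedVariant] = []
    for i, row in enumerate(frame.to_dict("records")):
        line = i + 2  # 1-based, after the header line
        try:
            tumor = VariantObservation(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                depth=int(row["tumor_depth"]),
                alt_reads=_opt_int(row.get("tumor_alt_reads")),
                vaf=float(row["tumor_vaf"]),
                quality=_opt_float(row.get("tumor_quality")),
                consequence=str(row.get("consequence") or OTHER),
                gene=str(row.get("gene") or ""),
                cdna_change=str(row["cdna_change"]) if row.get("cdna_change") else None,
                protein_change=(
                    str(row["protein_change"]) if row.get("protein_change") else None
                ),
                sift=str(row.get("sift") or "not_applicable"),
                polyphen=str(row.get("polyphen") or "not_applicable"),
                case_id=str(row["case_id"]),
            )
            normal_depth = _opt_int(row.get("normal_depth"))
            normal = None
            if normal_depth is not None:
                normal = VariantObservation(
                    chrom=tumor.chrom,
                    pos=tumor.pos,
                    ref=tumor.ref,
                    alt=tumor.alt,
                    depth=normal_depth,
                    alt_reads=_opt_int(row.get("normal_alt_reads")),
                    vaf=float(row["normal_vaf"]),
                    quality=_opt_float(row.get("normal_quality")),
                    consequence=tumor.consequence,
                    gene=tumor.gene,
                    case_id=tumor.case_id,
                )
            pairs.append(PairedVariant(tumor=tumor, normal=normal, case_id=str(row["case_id"])))
        except (ValueError, TypeError) as err:
            raise ValidationError(f"{source}: line {line}: {err}") from err
    return pairs


# ---------------------------------------------------------------------------
# VCF 4.2 dialect (via pysam)
# ---------------------------------------------------------------------------

_VCF_INFO_LINES = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CASE,Number=1,Type=String,Description="Case/sample label">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">',
    '##INFO=<ID=CDNA,Number=1,Type=String,Description="HGVS cDNA change">',
    '##INFO=<ID=PROT,Number=1,Type=String,Description="HGVS protein change">',
    '##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT category">',
    '##INFO=<ID=PPH2,Number=1,Type=String,Description="PolyPhen-2 category">',
]
_VCF_FORMAT_LINES = [
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
    '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Variant allele fraction">',
    '##FORMAT=<ID=NQ,Number=1,Type=Float,Description="Novel-allele mean quality">',
]


def _write_vcf(pairs: Sequence[PairedVariant], path: str) -> None:
    import pysam

    header = pysam.VariantHeader()
    seen: list[str] = []
    for pv in pairs:
        if pv.tumor.chrom not in seen:
            seen.append(pv.tumor.chrom)
    for chrom in seen:
        header.add_line(f"##contig=<ID={chrom}>")
    for line in _VCF_INFO_LINES + _VCF_FORMAT_LINES:
        header.add_line(line)
    header.add_sample("TUMOR")
    header.add_sample("NORMAL")

    def fill(sample, obs: Optional[VariantObservation]) -> None:
        if obs is None:
            return
        sample["DP"] = obs.depth
        if obs.alt_reads is not None:
            sample["AD"] = (obs.depth - obs.alt_reads, obs.alt_reads)
        sample["AF"] = obs.vaf
        if obs.quality is not None:
            sample["NQ"] = obs.quality

    with pysam.VariantFile(path, "w", header=header) as out:
        for pv in pairs:
            t = pv.tumor
            rec = out.new_record(
                contig=t.chrom, start=t.pos - 1, stop=t.pos, alleles=(t.ref, t.alt)
            )
            for key, value in (
                ("GENE", t.gene),
                ("CASE", pv.case_id),
                ("CSQ", t.consequence),
                ("CDNA", t.cdna_change),
                ("PROT", t.protein_change),
                ("SIFT", t.sift),
                ("PPH2", t.polyphen),
            ):
                if value:
                    rec.info[key] = value
            fill(rec.samples["TUMOR"], t)
            fill(rec.samples["NORMAL"], pv.normal)
            out.write(rec)


def _read_vcf(path: str) -> list[PairedVariant]:
    import pysam

    pairs: list[PairedVariant] = []
    with pysam.VariantFile(path) as vcf:
        if not {"TUMOR", "NORMAL"} <= set(vcf.header.samples):
            raise SchemaError(f"{path}: expected TUMOR and NORMAL sample columns")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValidationError(f"{path}: {rec.contig}:{rec.pos}: not biallelic")
            info = dict(rec.info)
            case_id = info.get("CASE") or ""
            shared = dict(
                chrom=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alts[0],
                consequence=info.get("CSQ") or OTHER,
                gene=info.get("GENE") or "",
                cdna_change=info.get("CDNA"),
                protein_change=info.get("PROT"),
                sift=info.get("SIFT") or "not_applicable",
                polyphen=info.get("PPH2") or "not_applicable",
                case_id=case_id,
            )

            def build(sample) -> Optional[VariantObservation]:
                if sample.get("DP") is None:
                    return None
                ad = sample.get("AD")
                quality = sample.get("NQ")
                return VariantObservation(
                    depth=int(sample["DP"]),
                    alt_reads=int(ad[1]) if ad is not None and ad[1] is not None else None,
                    vaf=float(sample["AF"]),
                    quality=float(quality) if quality is not None else None,
                    **shared,
                )

            tumor = build(rec.samples["TUMOR"])
            if tumor is None:
                raise ValidationError(
                    f"{path}: {rec.contig}:{rec.pos}: TUMOR sample has no depth"
                )
            pairs.append(
                PairedVariant(tumor=tumor, normal=build(rec.samples["NORMAL"]), case_id=case_id)
            )
    return pairs


# ---------------------------------------------------------------------------
# Public table I/O
# ---------------------------------------------------------------------------


def write_variant_table(
    pairs: Sequence[PairedVariant], path: str, dialect: str = "tsv"
) -> None:
    """Write paired variants to ``path`` in the ``tsv`` or ``vcf`` dialect."""
    if dialect == "tsv":
        pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
    elif dialect == "vcf":
        _write_vcf(list(pairs), str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_variant_table(path: str, dialect: str = "tsv") -> list[PairedVariant]:
    """Load paired variants from a ``tsv`` or ``vcf`` file, preserving row order.

    Raises :class:`SchemaError` for missing mandatory columns and
    :class:`ValidationError` (with the offending line number for TSV input)
    for field values that violate domain invariants.
    """
    if dialect == "tsv":
        frame = pd.read_csv(str(path), sep="\t", keep_default_na=False)
        return frame_to_pairs(frame, source=str(path))
    if dialect == "vcf":
        return _read_vcf(str(path))
    raise ValueError(f"unknown dialect {dialect!r}")
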