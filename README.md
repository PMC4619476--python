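# somaticmz

Somatic single-nucleotide variant (SNV) discovery analysis for paired
tumor/normal exomes of microdissected splenic marginal zone lymphoma (SMZL),
packaged as a reusable, tested Python library.

## The problem

SMZL is an indolent B-cell lymphoma with no signature diagnostic mutation.
Small discovery studies sequence laser-microdissected tumor cells and a
matched non-tumor control from the same spleen, call variants, and must then
separate true somatic mutations from germline polymorphisms, sequencing
noise and annotation chaff — all at modest depth (~47×) but very high tumor
purity (~0.88 from microdissection). The surviving call set is summarized
(mutation classes, transition/transversion spectrum, SIFT/PolyPhen-2
tallies), interpreted for clonality through variant allele fractions (VAF),
intersected with SNP-array copy-number segments, and followed up in a
targeted validation cohort.

`somaticmz` implements that full analysis path:

* **Filtering cascade** (`somatic_calling`) — consequence filter (drop
  intronic/UTR/synonymous, keep splice-site), a data-driven quality cutoff at
  mean − 2·sd of each calling's novel-allele qualities, the paired somatic
  rules (tumor depth ≥ 20, tumor VAF ≥ 0.1, normal VAF < 0.2,
  tumor − normal VAF ≥ 0.1), and a known-polymorphism blacklist — with a
  per-stage attrition report.
* **Call-set summaries** (`mutation_annotation`) — transition vs transversion
  (purine↔purine / pyrimidine↔pyrimidine vs the rest), mutation classes from
  HGVS-style change strings, per-case counts, prediction-category tallies.
* **Clonality and copy number** (`clonality_cna`) — VAF bins
  (subclonal ≤ 0.25 < intermediate < 0.35 ≤ clonal < 0.70 ≤ homozygous-like),
  segment filtering (≥ 5 SNP markers, ≥ 100 kb), closed-interval SNV–segment
  overlap, and a binomial likelihood ratio placing a mutation on the
  non-duplicated vs duplicated allele of a single-copy gain,
  LR = Binom(k; n, ⅓) / Binom(k; n, ⅔) = 2^(n−2k).
* **Cohort recurrence** (`cohort_recurrence`) — per-arm and pooled mutation
  frequencies with exact (Clopper–Pearson) confidence intervals.
* **Synthetic cohorts** (`synthetic_cohort`) — a generator of paired variant
  tables, copy-number profiles and validation genotyping tables with ground
  truth labels, using binomial read sampling at purity 0.88 and mean depth
  47×, so every stage is testable without any external data.
* **I/O and types** (`variant_io`) — typed records, HGVS substitution
  parsing, TSV and VCF 4.2 table round-trip, and a packaged 25-variant
  two-case discovery call set used throughout the tests and examples.

## Worked example

```bash
python examples/discovery_callset_summary.py
```

prints

```
somatic SNVs: 25 (per case: {'1': 12, '2': 13})
classes: {'missense': 23, 'nonsense': 1, 'splice_site': 1}
transitions/transversions: 64 % / 36 %
SIFT: {'damaging': 10, 'not_applicable': 1, 'stop_gained': 1, 'tolerated': 13}
PolyPhen-2: {'benign': 9, 'not_applicable': 3, 'possibly_damaging': 4, 'probably_damaging': 9}
clonality bins: {'clonal': 9, 'intermediate': 4, 'subclonal': 12}
```

i.e. of the 25 somatic SNVs (12 in case 1, 13 in case 2), 23 are missense,
one is a splice-site and one a nonsense change; 16/25 (64 %) are transitions;
SIFT calls 10 damaging and PolyPhen-2 calls 13 possibly/probably damaging;
and 12 of 25 variants have VAF ≤ 0.25 — likely subclonal, given that a
clonal heterozygous mutation at purity 0.88 is expected near VAF 0.44 —
while none reaches the ≥ 0.70 band that would suggest homozygosity.

The other examples exercise the cascade on a simulated pair
(`synthetic_cascade.py`), copy-number overlap and gain-allele placement
(`cna_overlap_and_placement.py` — a mutation seen in 14 of 50 reads inside a
3-copy gain gives LR = 2²² in favor of the non-duplicated allele), and the
validation-cohort arithmetic (`validation_recurrence.py` — e.g. MYD88 T794C:
3/24 validation samples = 12.5 %, pooled with discovery 4/26 = 15 %).

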