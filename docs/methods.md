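# Methods

This note documents the models, rules and numerical choices behind
`somaticmz`, and what the synthetic experiments do and do not demonstrate.

## Somatic filtering cascade

The cascade turns a table of paired tumor/normal variant calls into a somatic
call set in four ordered stages. Attrition is logged per stage so the effect
of the ordering is visible in the report rather than hidden.

1. **Consequence.** Calls annotated intronic, UTR or synonymous are removed;
   only variants that can change the protein are analyzed further.
   Splice-site calls are kept even when the codon is unchanged: the
   substitution can leave the amino acid intact while destroying the splice
   signal. The drop set is configurable (`FilterConfig.drop_consequences`).
2. **Quality.** Calls whose novel-allele mean quality falls below
   `mean − k·sd` of the qualities in the same calling are removed (`k = 2`
   by default). The threshold is computed per case/sample, not globally:
   it is meant to adapt to each run's quality distribution. The standard
   deviation is the sample sd (n−1 denominator); a single-element calling
   has sd 0. The quality unit is whatever the upstream caller emits; the
   rule only uses its empirical distribution.
3. **Somatic rules**, evaluated in a fixed order so the reported rejection
   reason is the first failing rule: tumor depth ≥ 20; tumor VAF ≥ 0.1;
   normal VAF < 0.2; tumor VAF − normal VAF ≥ 0.1. All "minimum/at least"
   thresholds are inclusive (≥); the normal-VAF cap is strict (<). A site
   with no normal observation is treated as normal VAF = 0 with a logged
   warning — the variant simply cannot be explained by the control — rather
   than as an error.
4. **Polymorphism.** Exact (chrom, pos, ref, alt) matches against a
   known-polymorphism locus list are removed.

**Idempotence caveat.** Because the quality threshold is recomputed from the
data entering the stage, a second pass over a previously filtered set can, in
principle, remove further variants (e.g. qualities {10, 12, 30×8}: the first
pass removes the 10, after which the 12 falls below the survivors' own
mean − 2·sd). The cascade is deliberately single-pass — that is the
procedure being modeled — and in practice re-running it on its own output is
a no-op for realistic quality distributions, which the tests check on
generator output and on the packaged call set. The pathological case above
is documented rather than "fixed" by iterating to a fixed point.

**Monotonicity.** Tightening any threshold (raising `min_coverage`,
`min_tumor_vaf`, `min_delta`; lowering `max_normal_vaf` or
`quality_sd_multiplier`; enlarging the drop set) never adds a variant to the
call set. Note the quality multiplier enters negatively: a *smaller* `k`
raises the cutoff. This holds because the quality stage population is fixed
by the (unchanged) consequence stage, and all later stages are per-variant
predicates. Enlarging `drop_consequences` changes the quality-stage
population, but only by removing members before a stage that keeps a
subset — so the final set still shrinks.

## Call-set summaries

Transitions are purine↔purine (A↔G) or pyrimidine↔pyrimidine (C↔T)
substitutions; everything else is a transversion. The classification is
symmetric and complement-invariant, so alleles read off the cDNA strand
classify identically to genomic ones — which is why the packaged call set
can store cDNA-strand alleles without affecting the Ti/Tv split.

Mutation classes come from HGVS-style strings: a protein change with
different residues is missense; an alternate residue `*` (or a stop-gained
flag) is nonsense; an unchanged residue is splice-site when flagged as such
and synonymous otherwise. Splice-site changes with unchanged codons count
once, as splice-site (no double counting with synonymous).

Display percentages round half-up to integer percent (`round_half_up`),
reproducing printed splits like 64 %/36 % from 16/9 of 25; unrounded values
are stored alongside. Per-arm cohort frequencies round to one decimal,
pooled headline frequencies to integer percent, matching reporting practice.

## Clonality bins

Tumor VAF partitions into: subclonal (VAF ≤ 0.25), intermediate
(0.25 < VAF < 0.35), clonal (0.35 ≤ VAF < 0.70), homozygous-like
(VAF ≥ 0.70). At purity p, a clonal heterozygous mutation on a diploid locus
has expected VAF p/2 ≈ 0.44 here, which motivates the 0.35–0.70 "clonal"
band. The lower clonal bound is **inclusive** at 0.35: the discovery call
set contains two variants at exactly 0.35, and only the inclusive reading
reproduces the published 9-of-25 count for the ≥ 35 % group; this is the one
place where a printed "> 35 %" is implemented as ≥. The subclonal bound is
inclusive per its "below or equal to 25 %" wording.

`estimate_purity` inverts the same model: twice the median VAF of clonal
calls estimates the tumor cell fraction. The median (not mean) resists the
lower-tail bias introduced by the VAF ≥ 0.1 calling floor.

## Copy-number segments and gain-allele placement

Segments use 1-based fully closed coordinates (the array platform's
convention is not standardized; closed intervals match the variant
convention and are documented here). Segments must carry ≥ 5 SNP markers
and span ≥ 100 kb to survive filtering, and must be disjoint per chromosome —
a sample has one copy-number state per locus — so overlap queries can return
at most one segment per variant. Overlap is `start ≤ pos ≤ end` on the same
chromosome, backed by an interval tree and cross-checked against a
brute-force scan in tests.

For a single-copy gain (3 total copies in a pure tumor), a heterozygous
mutation lies on the non-duplicated allele (expected VAF 1/3) or the
duplicated allele (expected VAF 2/3). With k variant reads out of n,

    LR = Binom(k; n, 1/3) / Binom(k; n, 2/3) = 2^(n − 2k),

because the binomial coefficients cancel and (1/3)^k (2/3)^(n−k) over
(2/3)^k (1/3)^(n−k) collapses to 2^(n−2k). The implementation evaluates the
ratio via `scipy.stats.binom.logpmf` differences (robust for large n); the
closed form is used as an independent check in tests. Calls are
`non_duplicated` above an ambiguity band, `duplicated` below it, and
`ambiguous` inside; the band defaults to [1/e, e] — about one unit of
log-likelihood, a conventional "barely worth mentioning" evidence margin.
The default comparison assumes a pure tumor; with purity p given, the
expected fractions become p·m / (2(1−p) + 3p) for allele multiplicity
m ∈ {1, 2}, which shrinks both fractions toward 0 and attenuates (but for
realistic purity does not flip) the evidence.

## Cohort recurrence

Per-arm frequencies are binomial proportions; pooled frequencies pool
counts, so they are the sample-size-weighted mean of the arm frequencies.
Pooling the two discovery exomes with validation samples treats all cases as
exchangeable draws from one patient population. Denominators follow the
screening design: 2 + 24 = 26 for the pyrosequenced site, 2 + 8 = 10 for the
Sanger-screened genes (validation by Sanger was only possible in the eight
fresh-tissue cases). Confidence intervals are exact Clopper–Pearson
(`statsmodels`, method `beta`), checked in tests against direct beta
inverse-CDF evaluation; `failed` assays are excluded from denominators with
a returned count.

## Synthetic cohort generator

The generator emulates the statistical structure of one microdissected
tumor/normal exome pair, not its sequence content. Per locus it draws depths
from Poisson(47) (negative binomial behind a flag for overdispersion;
`var = µ + µ²/size`) and alt reads binomially:

| origin        | tumor success fraction              | normal success fraction |
|---------------|-------------------------------------|-------------------------|
| germline het  | 0.5                                 | 0.5                     |
| somatic       | purity·CCF/2 (diploid loci)         | error rate              |
| artifact      | error rate                          | 0                       |
| polymorphism  | 0.5                                 | 0.5, or error rate under allele dropout |

Defaults encode the study conditions: purity 0.88 (microdissection yields
87–89 % tumor cells), mean depth 47×, CCF mixture
{1.0: 0.5, 0.5: 0.3, 0.25: 0.2} (half the somatic burden clonal, the rest
subclonal), per-base error rate 10⁻³ (a platform-agnostic stand-in;
configurable). Inside a simulated gain, the somatic success fraction becomes
purity·CCF·m / (2(1−purity) + 3·purity) with multiplicity m = 2 on the
duplicated allele (probability 1/2) and m = 1 otherwise. The copy-number
profile analog is one 3q-like gain and one 7q-like loss, both far above the
marker/length floors, plus optional sub-threshold decoys; marker counts
assume ~one array SNP per 7 kb.

Qualities: true variants draw novel-allele qualities uniformly over the
observed calling range (17–32); artifacts over a lower band (8–20). A
uniform distribution's mean − 2·sd lies below its minimum
((b−a)/√12 · 2 < (b−a)/2), so the data-driven quality filter never clips
true variants — consistent with an observed call set in which every retained
variant passed that filter — while artifacts mixed in from the lower band
are partially removed. Polymorphisms suffer normal-sample allele dropout at
rate 0.5, so about half of them masquerade as somatic and must be caught by
the blacklist stage; without dropout the normal-VAF rule would remove them
all and the blacklist stage would be untestable end-to-end.

Default locus counts per pair (1000 germline het, 25 somatic, 50 artifacts,
100 polymorphisms) keep unit runs fast; the end-to-end experiments scale the
counts up (9000/500/400/100, ~10⁴ loci) to measure rates precisely. These
are the problem sizes used throughout the tests and the acceptance script.

**What the generator does not model:** read-level data (no FASTQ/BAM, no
mapping artifacts), error substitution spectra, FFPE deamination damage,
copy-number noise in the stromal compartment, and correlated errors between
tumor and normal. Passing recovery/rejection tests therefore demonstrates
that the rule set behaves correctly under binomial sampling at the stated
depth and purity — not that it is robust to artifact classes the binomial
model cannot produce.

## End-to-end expectations under the defaults

At depth 47 and purity 0.88 a clonal somatic variant has expected VAF 0.44;
the probabilities of failing the coverage, VAF-floor or delta rules are
binomial tail events (each ≪ 1 %), so clonal recovery ≥ 99 % is a property
of the thresholds, verified empirically over ~10⁴ loci. A germline het
passes the normal-VAF rule only if Binom(47, 0.5)/47 < 0.2, about a 4σ
event, so germline rejection ≥ 99 % likewise follows. Purity re-estimation
(2 × median recovered clonal VAF) is evaluated over 20 replicate cohorts of
50 somatic variants; the per-replicate estimator has sampling sd ≈ 0.036, so
the ±0.05 accuracy claim is made for the aggregate (mean over replicates,
sampling sd ≈ 0.008), not for every single replicate.

## Numerical and interface choices

* Coordinates 1-based fully closed everywhere; VCF output is VCF 4.2 with
  `TUMOR`/`NORMAL` sample columns (`DP`, `AD` as ref/alt pair, `AF`, `NQ`);
  the TSV dialect mirrors the discovery call-set columns. Round-trips
  preserve integers and strings exactly and fractions to 6 decimals (VCF
  text serializes floats at ~6–7 significant digits).
* Stored VAFs must agree with `alt_reads/depth` to 0.005 — the slack a
  two-decimal printed VAF needs.
* HGVS whitespace is normalized before parsing; only single-base
  substitutions are modeled, and indels raise parse errors identifying the
  offending token.
* `round_half_up` operates on the decimal repr to avoid binary-float tie
  artifacts; Python's built-in banker's rounding would print 12.5 % → 12 %.
* The packaged discovery table stores positions with thousands separators
  stripped; one record's exon/coverage field pair is ambiguous in the
  source layout and is stored as coverage 61 with a missing exon (the only
  reading compatible with the pipeline's own coverage ≥ 20 rule). Exon
  numbers are carried as metadata and used in no computation.
* SIFT categories include `stop_gained` alongside damaging/tolerated/NA:
  predictors do not score truncating changes, and call sets print them as
  their own category; tallies keep it separate so "damaging" counts are not
  inflated.
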