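# Methods

This note documents the statistical model behind `varscreen`, the numerical
conventions it fixes, what the synthetic-data generator does and does not
emulate, and the design choices that were genuinely open.

## Screening model

The pipeline treats a jointly-genotyped diploid cohort as the unit of
analysis. Variants are monoallelic records keyed by `chrom_pos_ref_alt`
(1-based, `chr`-prefixed, left-normalized); multiallelic VCF records are
decomposed on read, with each row's dosage counting only the focal alternate
allele while every called allele contributes to AN. AC and AN are always
recomputed from genotypes; INFO fields are never trusted.

The screening cascade is: restrict to cancer-gene regions (gene intervals
padded symmetrically, default 10 kb, membership by the variant's position in
the closed padded interval) → classify impact from Sequence Ontology
consequence terms (max-severity over terms via a shipped, editable table;
unknown terms are MODIFIER) → bucket ClinVar-style labels into P/LP, VUS,
conflicting, benign/likely-benign or unclassified (case-insensitive,
spaces/underscores interchangeable) → optionally filter on PHRED-scaled CADD
(default ≥ 20, i.e. the top 1% most deleterious substitutions; unscored
variants are excluded, not imputed, and counted in a log line). Each stage
only removes variants and is idempotent.

## Cohort statistics

* `AF = AC/AN`, `MAF = min(AF, 1 − AF)`; *rare* means MAF < 0.01 (MAF, not
  AF, so a near-fixed site is still "rare" on its minor allele); *singleton*
  means AC = 1.
* Carrier prevalence of a variant set: a sample is positive iff its dosage is
  ≥ 1 at any set member; heterozygotes and homozygotes count once, as does a
  sample carrying several set variants.
* Combined set AF: Σ AC over the set divided by the cohort allele pool. With
  complete genotypes the pool is the shared AN (2N); with per-variant
  missingness the mean AN over the set is used. Dividing by Σ AN across k
  variants would shrink the quantity by a factor k and would not match the
  carrier-count interpretation (9 alleles among 2152 → 0.42%), so it is not
  used.
* Percentages are printed half-up at two decimals; enrichment ratios at two
  significant figures (half-up). These conventions are fixed so that report
  output is deterministic and matches the precision such screens
  conventionally publish.

## Enrichment test

For each variant the enrichment statistic is the allele-frequency ratio
`AF_cohort / AF_panel`. It is reported in a column named `af_ratio_or`
because screens of this kind conventionally label it "OR"; it is not an
odds ratio (it is a risk-ratio-style quantity on allele frequencies), and at
the low frequencies where it matters the two are numerically close.

Testing order is fixed: (1) keep HIGH/MODERATE-impact variants; (2) keep
variants present in the chosen reference panel with AF > 0 — absent or
AF = 0 variants go to a "cohort-only" sidecar rather than being tested
(a ratio against zero is undefined); (3) build the 2×2 allele-count table;
(4) Bonferroni over the m variants actually tested, family-wise α = 0.05.

Reference panels publish frequencies and allele numbers, not per-variant
integer counts, so the panel's alternate count is reconstructed as
round-half-up(AF × AN). The exact test needs counts; this reconstruction is
exact whenever the published AF was itself computed as AC/AN.

The two-sided Fisher exact p-value uses the minimum-likelihood definition:
the sum of point hypergeometric probabilities not exceeding the observed
table's, with a 1e-7 relative gate on the comparison to absorb floating-point
ties. Probabilities are accumulated from a cached log-factorial table, which
is stable at panel allele numbers around 1e5. The test suite checks this
implementation two independent ways: against an exact integer-arithmetic
enumeration oracle for every table with margins ≤ 60 (agreement within
1e-9), and against `scipy.stats.fisher_exact` on spot tables. A one-sided
(enrichment-only) alternative is available behind a flag; two-sided is the
default because it is the dominant convention when sidedness is not
pre-registered.

Bonferroni uses m = the number of variants actually tested, not the full
variant count: the correction is over the hypotheses actually evaluated
after the impact and panel-presence filters.

## Ancestry sharing

A set variant is shared with an ancestry panel iff a record for that
(source, panel, variant) exists with AF > 0; it is cohort-unique
(monomorphic elsewhere) iff no panel of that source has it at AF > 0. Absent
records count as AF = 0, which makes "absent" and "recorded at zero"
equivalent — a single definition covering both readings of
"unique/monomorphic". Matching is by exact variant key; no liftover or
allele-flip rescue is attempted, since cross-database comparisons here
assume same-build, normalized keys. Counts are computed independently per
source, so unique counts are expected to differ strongly with database
coverage.

## Synthetic cohorts

The generator emulates the features the statistics above actually depend on:

* per-site genotypes under Hardy–Weinberg equilibrium, dosage ~
  Binomial(2, AF), independent across sites and individuals;
* founder-like sites with an exact number of het/hom carriers. Carriers are
  placed disjointly across all injected sites (drawn from one seeded
  permutation of the cohort), modelling distinct founder lineages and making
  printed carrier counts deterministic — nine injected alleles are always
  nine carriers;
* i.i.d. genotype missingness at a configurable rate (default 0; injected
  sites are never masked so their counts stay exact);
* matching gene-interval, annotation and multi-source panel tables, written
  as a bundle with a manifest recording the seed, a config hash, per-file
  checksums and the simulated truth.

One global seed drives everything; each site's stream is derived from a
SHA-256 hash of its variant key mixed with the seed, so adding a site never
perturbs the genotypes of existing sites.

The default cohort size is 1076 individuals (2152 alleles), the scale of a
national unrelated-donor WGS cohort, and the default demo scenario contains
seven P/LP breast-cancer-gene variants (nine carriers; combined AF 0.42%,
founder subset 0.23%), three reference-enriched sites whose AF ratios print
as 130, 220 and 130 at two significant figures, Hardy–Weinberg null sites
frequency-matched to their panel records, and ancestry panels giving
5/7, 3/7, 2/7, 1/7, 1/7 sharing with one database and complete cohort
uniqueness against another.

What the generator does **not** emulate: linkage disequilibrium (the
statistics here are single-site), relatedness or population substructure,
sequencing or genotyping error, transcript-level annotation ambiguity, and
reference-panel sampling noise (panel AFs are taken as fixed). Passing tests
therefore validate the pipeline's arithmetic and inference under its stated
assumptions; they do not certify behavior on cohorts with cryptic
relatedness or discordant annotation sources.

## Numerical and edge-case conventions

* Half-called genotypes (`./1`) contribute their called allele to AC and one
  allele to AN. Variants with AN = 0 are dropped with a warning.
* Ref/alt pairs sharing more than one base of combined leading+trailing
  context are rejected as un-normalized; left-normalization itself is the
  caller's responsibility (standard VCF toolchains provide it upstream).
* Degenerate exact-test margins (an empty row or column) return p = 1.
* The singleton fraction of an empty rare set is reported as NA, not 0.
* Interval membership at the padded boundary is inclusive on both ends;
  padded starts clamp at position 1.
* Reports are byte-deterministic: fixed column order, rows sorted by
  (chrom, pos, ref, alt); run manifests carry timestamps but reports do not.

## Problem sizes used in the checks

The shipped verification uses a 1076-individual demo cohort (~16 sites), an
exhaustive exact-test sweep over all 2×2 tables with row margins ≤ 60
(~3.6 M tables), a 2000-replicate binomial null calibration at panel AFs of
0.01 and 0.1, a 100-seed × 60-site Hardy–Weinberg recovery study, and a
12 836-variant constructed cohort for the singleton-fraction summary. These
sizes give stable answers for every quantity checked while keeping a full
run in the low minutes on one core.

## Known limitations

* The enrichment statistic inherits the reconstruction error of
  round(AF × AN) when a panel publishes rounded frequencies; with heavily
  rounded inputs the printed ratio can differ from one computed on the
  panel's true counts.
* Bonferroni is conservative for correlated tests; no FDR alternative is
  currently exposed.
* Impact classification is per-variant, not per-transcript; a variant's most
  severe consequence across transcripts should be precomputed upstream.
* The "low" impact bucket is kept distinct from MODIFIER even though
  published three-way summaries may merge them; both counts are reported so
  either convention can be recovered.
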