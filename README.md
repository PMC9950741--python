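# varscreen

Population-scale **germline cancer-variant screening** for cohort VCFs.

`varscreen` is for groups that hold a jointly-genotyped population cohort
(hundreds to thousands of unrelated, unselected individuals) and want to ask
the questions a national-genome cancer screen asks:

* Which variants fall in (padded) cancer-gene regions, and how do they break
  down by Sequence Ontology impact, ClinVar pathogenicity and CADD
  deleteriousness?
* What are the cohort allele frequencies, which variants are rare
  (MAF < 0.01), which are singletons, and what fraction of the rare spectrum
  do singletons make up?
* How prevalent are carriers of a pathogenic variant set (e.g. all ClinVar
  P/LP *BRCA1*/*BRCA2* alleles), and what is the set's combined allele
  frequency?
* Which variants are **enriched** relative to a reference panel such as
  gnomAD non-Finnish Europeans, and which of those survive multiple-testing
  correction?
* How much of the cohort's variation is shared with other ancestries
  (AFR/AMR/EAS/SAS/EUR) across reference databases, and how much is
  cohort-unique (monomorphic elsewhere)?

## The statistics

For a variant with alternate-allele count AC and called-allele number AN
(missing genotypes reduce AN, they are never imputed):

* allele frequency `AF = AC / AN`, minor allele frequency
  `MAF = min(AF, 1 − AF)`; *rare* means `MAF < 0.01`, *singleton* means
  `AC = 1`;
* carrier prevalence of a variant set = (samples with ≥ 1 alt allele at any
  set member) / (samples tested);
* combined set AF = Σ AC over the set divided by the cohort allele pool
  (2N for complete genotypes);
* the enrichment statistic for a variant against a reference panel is the
  allele-frequency ratio `AF_cohort / AF_panel` (reported as "OR" by
  convention in the report column `af_ratio_or`, printed at two significant
  figures);
* significance comes from a two-sided **Fisher exact test** on the 2×2
  allele-count table (panel counts reconstructed as round(AF × AN)), with
  **Bonferroni** correction over the m variants actually tested and
  family-wise α = 0.05;
* a variant is *shared* with an ancestry panel iff that panel records it with
  AF > 0, and *cohort-unique* iff no panel of the reference database does.

A seeded synthetic-cohort generator (`varscreen simulate`) draws genotypes
under Hardy–Weinberg equilibrium, injects founder-like variants with exact
carrier counts, and emits matching gene/annotation/panel tables, so the whole
pipeline is exercisable without access-controlled cohort data.

## Worked example

```bash
varscreen simulate --out demo --seed 1
varscreen screen --vcf demo/cohort.vcf --genes demo/genes.tsv \
                 --annotations demo/annotations.tsv --out demo/screen
varscreen enrich --vcf demo/cohort.vcf --genes demo/genes.tsv \
                 --annotations demo/annotations.tsv --panels demo/panels.tsv \
                 --source gnomADe --out demo/enrich
varscreen share  --vcf demo/cohort.vcf --panels demo/panels.tsv --out demo/share
```

The demo cohort holds 1076 diploid individuals with seven injected
pathogenic/likely-pathogenic *BRCA1*/*BRCA2*-like variants (nine
heterozygous carriers in total) plus enriched and null sites. In Python:

```python
>>> import varscreen as vs
>>> cfg = vs.demo_config(seed=1)
>>> table = vs.simulate_cohort(cfg)
>>> plp = vs.demo_plp_keys()
>>> vs.carrier_prevalence(table, plp)
(9, 0.008364312267657992)
>>> vs.format_pct(vs.combined_set_af(table, plp))
'0.42'
>>> vs.format_pct(vs.combined_set_af(table, vs.demo_founder_keys()))
'0.23'
```

That is: 9 of 1076 individuals carry a P/LP allele; the combined set AF is
9/2152 → **0.42%**, and the three founder-like alleles alone give 5/2152 →
**0.23%**. The first rows of `demo/enrich/enrichment.tsv` show the injected
enriched sites:

```text
variant_key        gene   impact    af_cohort  af_panel  af_ratio_or  p_bonferroni  significant
chr9_95126582_C_G  FANCC  HIGH      0.0023234  1.8e-05   130          1.088e-06     True
chr3_195779189_C_G MUC4   MODERATE  0.0120818  5.4e-05   220          4.459e-38     True
chr17_5132920_G_A  USP6   MODERATE  0.0023234  1.8e-05   130          1.088e-06     True
```

`af_ratio_or = 130` means the cohort frequency is ~130× the reference-panel
frequency and the Bonferroni-adjusted exact-test p-value is far below 0.05.
`demo/share/sharing.tsv` reports, per reference database, how many of the
variants each ancestry panel shares and how many are cohort-unique.

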