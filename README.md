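# tric4

Analysis pipeline linking an *HLA-DRA* intron-1 three-SNP haplotype
("tri-SNP": rs3135394, rs9268645, rs3129877, coded over {0,1} with
0 = reference) to autoimmunity outcomes and to complement C4A/C4B gene
copy number. Because the source cohort is controlled-access, every stage
is exercised against a first-class synthetic cohort generator that
reproduces the statistical structure the analysis assumes.

## Modules

| module | what it does |
|---|---|
| `tric4.haplotypes` | tri-SNP genotype calling from phased variants, B8-DR3 dosage imputation (mode over a tag panel), HLA × tri-SNP cross-tabulation and chromosome-level haplotype accounting |
| `tric4.c4` | paralog-aware C4 copy-number calling from windowed WGS depth: flank-normalized (diploid = 2) coverage, total-GCN thresholds (1.4 / 1.9), unique-region C4A/C4B split heuristic |
| `tric4.association` | labeled contingency tables, Pearson chi-squared (no continuity correction), exact fraction summaries |
| `tric4.survival` | endpoint censoring rules (T1D, IA, IAA-first, GADA-first, CD, CDA), iterated category filtering (<20 members, zero events/non-events), Cox PH fits (lifelines, Efron ties) full-cohort and DR3-homozygous |
| `tric4.expression` | CPM, per-individual median aggregation, per-gene log2-CPM dosage trend with BH adjustment |
| `tric4.cohort` | synthetic study generator: linked haplotypes (HLA / tri-SNP / C4 structure / B8), Weibull proportional-hazards outcomes, coverage profiles, negative-binomial expression, text fixture bundles |
| `tric4.reference` | bundled published aggregate tables used as validation oracles and generator defaults |

## CLI

```sh
simulate --seed 42 --n 2000 --out fixtures/        # or: tric4 simulate ...
call-trisnp --vcf fixtures/genotypes.vcf --out calls.tsv
crosstab --calls calls.tsv --meta fixtures/meta.tsv --out table1.tsv
call-c4 --coverage fixtures/coverage.tsv --windows fixtures/windows.bed --out c4_calls.tsv
associate --calls c4_calls.tsv --trisnp calls.tsv --paralog A --out assoc.json
survival --meta fixtures/meta.tsv --out fits/
expression --counts fixtures/counts.tsv --covars fixtures/covars.tsv --out trend.tsv
```

Each command is also available as a `tric4` subcommand. `call-trisnp`
accepts `--sites sites.yaml` to override the site alleles; `call-c4`
accepts `--config c4.yaml` for region/threshold overrides.

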