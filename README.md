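# eightplex

Rule-based prediction of human eye color (brown / green / blue / not blue /
not brown) and skin color (light / not dark / not light) from genotypes at a
panel of eight SNPs:

| rsID | gene | alleles | eye | skin |
|------|------|---------|-----|------|
| rs12913832 | HERC2 | A/G | x | x |
| rs16891982 | SLC45A2 | C/G | x | x |
| rs6119471 | ASIP | C/G | x | x |
| rs12203592 | IRF4 | C/T | x | |
| rs12896399 | SLC24A4 | G/T | x | |
| rs1426654 | SLC24A5 | A/G | | x |
| rs885479 | MC1R | A/G | | x |
| rs1545397 | OCA2 | A/T | | x |

Eye color is decided in two steps. Step 1 anchors on rs12913832 (A/A or A/G
→ *not blue*; G/G → *not brown*) and refines to a positive color through
homozygous genotypes at rs6119471, rs16891982, and rs12203592. Step 2
re-examines samples left with only a negative description: rs12913832 G/G
plus rs12896399 T/T upgrades to *blue*, rs12913832 A/A plus rs12896399 G/G
to *brown*. The legacy `7plex` mode skips step 2. Skin color is an
elimination over homozygotes only: any two of five light-associated
homozygous genotypes give *not dark*, a stricter three-marker combination
gives *light*, and rs6119471 G/G gives *not light*; otherwise the result is
*inconclusive* (or *conflict* if light- and dark-branch rules co-fire).

The package also ships:

- machine-readable fixtures of the reference training (n=803) and test
  (n=212) outcome tables, with an engine that reproduces all derived
  summary numbers (`eightplex verify-tables`),
- generic association statistics (chi-square test of independence with
  Cramér's V, unweighted Cohen's kappa, pooled two-proportion z-test),
- a seeded synthetic cohort simulator (Hardy-Weinberg genotypes per
  population, truth phenotypes with a configurable discordance rate).

## CLI

```sh
# per-sample predictions from a VCF (matched by rsID, with a GRCh38
# positional fallback) or a genotype TSV
eightplex predict --vcf cohort.vcf --out predictions.tsv
eightplex predict --genotypes cohort.tsv --mode 7plex

# score predictions against a phenotype table
# (sample_id / population / eye_bin / skin_bin)
eightplex evaluate --genotypes cohort.tsv --phenotypes truth.tsv

# synthetic cohort: genotype TSV + phenotype TSV + manifest (+ VCF)
eightplex simulate --n 1000 --epsilon 0.05 --seed 7 --out cohort/ --vcf

# recompute the packaged outcome-table numbers, PASS/FAIL per target
eightplex verify-tables [--json]
```

Exit codes: 0 success, 1 usage error, 2 data/validation error.

The genotype TSV dialect is a header `sample_id` plus one column per rsID,
with cells like `A/G` (order irrelevant) or `NA`/`./.` for missing.
Opposite-strand input is auto-complemented with a warning for
non-ambiguous SNPs only; C/G and A/T SNPs are never silently flipped.

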