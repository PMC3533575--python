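# alfasnp

SNP discovery, ploidy-aware genotyping and diversity analysis for
mixed-ploidy alfalfa (*Medicago sativa*) panels, starting from per-site
allele read-count tables.

Breeders and population geneticists working with autotetraploid crops
face two problems this package addresses. First, calling SNPs from
multi-sample transcriptome read counts requires filters that separate
real segregating variants from sequencing error without a reference
genotype panel. Second, downstream diversity questions — how much
polymorphism survives in elite germplasm, which genes are fixed by
domestication, how the panel is structured — must be answered on
dosage-lumped genotype calls, because short reads cannot reliably
distinguish the tetraploid heterozygous classes ABBB, AABB and AAAB.

## Method

A candidate variant site with per-genotype reference/variant read counts
(r_g, v_g) and mean variant-base quality q_g is kept as a SNP iff, in
cascade order:

1. **sample support** — ∃ g with v_g ≥ 2, q_g ≥ 20 and
   v_g/(r_g+v_g) ≥ 0.20;
2. **total depth** — Σ_g (r_g+v_g) > 20 (strict);
3. **genotypic contingency test** — Pearson's χ² on the 2×K table of
   (reference, variant) counts over the K genotypes with reads
   (df = K−1) rejects independence at p < 0.01. Uniform sequencing
   error is independent of genotype and fails; genuine segregation
   shows genotype-specific allele proportions. A seeded permutation
   alternative (shuffling allele labels among reads, preserving
   per-genotype depths) is available for sparse tables.

PASS SNPs with ≥ 10 reads in **every** genotype form the *core set*.
Each entry is classified AA / AB / BB from the variant read fraction f:
f ≤ 0.10 → AA, f ≥ 0.90 → BB, otherwise AB when both alleles carry
≥ 2 reads. Heterozygosity per genotype is #AB / #classified.
Group-level accounting (polymorphism Venn regions, fixed differences,
candidate contigs with ≥ 5 private-polymorphism SNPs) operates on this
matrix, as do population-structure analyses: simple matching distance
(1 − fraction of identically classified sites), classical unweighted
Saitou–Nei neighbor joining with Newick export, and PCA (states coded
0/1/2, site-centered SVD).

A synthetic-panel generator with known truth (Balding–Nichols
group-structured allele frequencies, tetrasomic/disomic Hardy–Weinberg
dosages, overdispersed read depth, per-read miscalls) makes every stage
testable without sequencing data.

## Worked example

Run the self-contained demo (a simulated 27-genotype panel — 16 elite
tetraploids in four breeding-program subgroups, 6 tetraploid mapping
parents, 5 wild genotypes including four diploids — at 2,000 sites):

```bash
alfasnp run-all --out demo --seed 42
```

The JSON report printed at the end includes (seed 42):

```
"sites_in": 2000
"calls": {"pass": 1682, "pass_snps": 1628, "pass_indels": 54,
          "fail_sample_support": 171, "fail_total_depth": 0,
          "fail_contingency": 147}
"core_set_size": 1463
"hrm_eligible": 1193
```

2,000 simulated sites enter the cascade; 171 fail sample support (no
genotype shows the variant convincingly), 147 fail the contingency test
(allele counts independent of genotype — the error-like sites), and
1,682 PASS. Of the 1,628 PASS SNPs, 1,463 have ≥ 10 reads in all 27
genotypes and form the core set. 1,193 PASS SNPs have 18-bp
polymorphism-free flanks and are eligible for HRM assay design.
Per-genotype heterozygosity lands where tetrasomic/disomic expectation
puts it — e.g. 54.4% for elite tetraploid `CW-1`, 21.3% for the diploid
`CAE-1`, and 36.5% for the two pooled caerulea diploids treated as one
four-chromosome individual. The first two PCs explain 17.8% and 7.2% of
the variance and separate the wild group; the NJ tree (`demo/tree.nwk`)
recovers all three groups as clades.

The same stages are available piecewise (`alfasnp simulate`, `call`,
`genotype`, `partition`, `structure`, `validate-summary`), and as
library functions under `alfasnp.filtering`, `alfasnp.genotyping`,
`alfasnp.diversity` and `alfasnp.structure`.

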