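# Methods

## Scope and data model

`alfasnp` starts downstream of read alignment: its input is a per-site,
per-genotype table of reference-allele read counts, variant-allele read
counts and mean variant-base Phred quality, keyed by contig and 0-based
position, plus a group/ploidy configuration and contig metadata
(lengths, optional anchor coordinates on a reference pseudomolecule).
Alignment, assembly and initial variant detection are out of scope.
Sites are strictly biallelic; insertion/deletion variants travel through
the same filter path (class `InDel`, recognised by allele length) but
are excluded from the genotype matrix and all diversity statistics.
Internal coordinates are 0-based half-open everywhere; VCF export
converts to 1-based.

## Filter cascade

A site is called a variant iff it passes, in order: (1) *sample
support* — at least one genotype carries the variant on ≥ 2 reads with
mean variant-base quality ≥ 20 and variant read fraction ≥ 0.20 (all
boundaries inclusive); (2) *total depth* — summed reads across
genotypes strictly greater than 20; (3) *genotypic contingency test* —
p < 0.01. The verdict records the first failing stage, and per-stage
diagnostics are kept for every site.

Boundary semantics deserve emphasis because they are easy to drift on:
"at least 2 reads", "at least 20" quality and "20% frequency" are ≥;
the total-read rule is a strict >. The variant fraction uses the
two-allele denominator r+v; reads carrying third alleles are outside
the data model.

### Contingency test

The test asks whether allele identity (reference vs variant) is
independent of genotype in the 2×K read-count table, K being the
genotypes with nonzero depth at the site. Uniform sequencing error
gives every genotype the same expected variant fraction — independence
— while true segregation concentrates variant reads in carrier
genotypes. The default statistic is Pearson's χ² with df = K−1;
genotypes with zero depth are dropped (a zero column makes expected
counts zero and the statistic undefined). Degenerate tables (K < 2, or
an allele row summing to zero) carry no evidence and are assigned
p = 1, which also means a site monomorphic-variant across the panel
(all BB) is *not* called: the pipeline detects segregating sites.

The permutation mode shuffles allele labels among all reads, preserving
per-genotype depths, and reports p = (1 + #{T_perm ≥ T_obs}) / (1 + B).
It is the exact conditional test up to Monte-Carlo error and is the
recommended option for sparse tables. A caveat established during
validation: with expected cells only slightly above 5 and few columns,
the χ² tail and the exact conditional p can differ by ~0.01–0.02 — a
systematic asymptotic-approximation gap that no number of permutations
removes. At this package's target regime (tens of genotype columns at
~40–70 reads each) the two agree within Monte-Carlo noise, and the
acceptance suite checks calibration in exactly that regime.

## Genotype classification

No published rule exists for converting read counts to AA/AB/BB calls
at these depths, so the classification is this package's own design,
exposed in `CallParams`: depth < 10 → missing; variant fraction
f ≤ 0.10 → AA; f ≥ 0.90 → BB; otherwise AB provided each allele has
≥ 2 reads, else missing. The 0.10 homozygote band with the 2-read
requirement was chosen so a single miscalled read at the 10-read floor
cannot fabricate a heterozygote (1/10 = 0.10 is still AA), while a true
tetraploid single-dose heterozygote (expected fraction 0.25) is
comfortably inside the AB band. Heterozygous dosage classes are
deliberately lumped: at ~50× depth the ABBB/AABB/AAAB split cannot be
resolved reliably, and no dosage estimation is attempted.

The *core set* keeps PASS SNPs with depth ≥ 10 in every genotype, so
every per-genotype statistic rests on the same sites; with the default
thresholds the resulting matrix is fully classified (no missing
entries). Heterozygosity is #AB / #classified per genotype, in percent.
Two diploids of one subspecies can be pooled into a synthetic
four-chromosome individual (missing if either is missing; AB if either
is AB or the homozygous states differ) to compare wild diploids against
tetraploids on one scale.

## Diversity partition

A SNP is *polymorphic within a group* iff among the group's non-missing
calls at least one is AB or two are opposite homozygotes — defined on
calls, not raw reads. Venn regions are the 2^k−1 exclusive membership
patterns over k groups; sites where any group has no non-missing call
are excluded from the totals (and counted in the log). Fixed
differences require all non-missing calls AA in one group and BB in the
other. Candidate contigs collect SNPs polymorphic within a pooled
genotype set (so a difference *between* two wild genotypes counts) yet
monomorphic-homozygous across every genotype of a second set; contigs
with ≥ 5 qualifying SNPs are reported. SNP density is counted in
fixed-origin, half-open 0.5-Mbp windows along anchor chromosomes, as
SNPs per kbp; windows are tiles, not sliding.

## Population structure

Simple matching distance: 1 − (identically classified sites)/(sites
where both calls are non-missing), an exact-match metric over the
states {AA, AB, BB}; a pair with no comparable sites is an error, not a
NaN. Neighbor joining is the classical Saitou–Nei agglomeration
(PHYLIP's unweighted default): join the pair minimising
Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·), standard limb-length
formulas, exact Q-ties broken by the lexicographically smallest sorted
pair of subtree leaf labels so genotype order never changes the result.
Negative branch lengths are retained by default (clamping is optional).
Newick output uses 6-decimal fixed branch lengths and quotes labels
containing spaces. PCA codes states 0/1/2, imputes missing entries with
the site mean (a no-op on the core set), centers each site and
decomposes by SVD; variance fractions are λ_k/Σλ.

## Synthetic panel generator

The generator defines the conditions every downstream test runs under.
Defaults mirror the target panel design: 27 genotypes — 16 elite
tetraploids in four breeding-program subgroups of four, 6 tetraploid
mapping parents, 5 wild genotypes (2 diploid caerulea, 2 diploid
falcata, 1 tetraploid falcata) — on 200 contigs of 1,065 bp (the
study-scale average transcript length) with 10 sites each.

Per site: ancestral variant frequency p ~ Beta(0.5, 0.5) by default — a
U-shaped site-frequency spectrum chosen because it reproduces
study-like heterozygosity (roughly 20–28% in diploids, 35–55% in
tetraploids); a uniform law is available. Group frequencies drift from
p under Balding–Nichols: Beta(p(1−F)/F, (1−p)(1−F)/F) with per-group F,
defaults (0.05, 0.05, 0.30) — the two cultivated groups close, the wild
group divergent; F = 0 copies p, F = 1 is rejected as degenerate.
Dosages are Binomial(ploidy, group frequency), i.e. tetrasomic/disomic
Hardy–Weinberg within groups. Read depth is negative binomial with mean
56 (the study-scale average per-genotype depth) and dispersion 5,
reflecting overdispersed transcriptome coverage; Poisson is the
dispersion→∞ limit. Each read reports the variant allele with
probability dosage/ploidy, flipped with miscall probability 0.005; the
recorded mean variant-base quality is Gaussian (mean 30, sd 5,
truncated at 0) and set to 0 when no variant read exists. About 3.5% of
sites are simulated as single-base insertions (the study-scale
InDel:SNP ratio), and 65% of contigs get anchor coordinates on eight
50-Mbp chromosomes.

What the generator does *not* emulate: linkage disequilibrium along
contigs (sites are independent), allele-specific expression,
read-mapping artefacts, multi-allelic sites, and pooled-progeny bulks
(the real panel's two French parents were sequenced as bulks of three
selfed progeny; absent a defensible mixing model a plain tetraploid
stands in). Passing tests therefore demonstrate correctness of the
statistical machinery under idealised sampling, not robustness to
alignment error or expression bias.

Determinism contract: one `numpy` generator seeded from the config
drives all stages in a fixed order, and all writers use fixed formats,
so an identical config reproduces output files byte for byte.

## Problem sizes and numerical choices

The published panel's headline counts derive from ~700 M reads and are
not reproducible at desk scale; the test and acceptance workloads use
simulated panels of 2,000–20,000 sites, chosen so the whole suite runs
in seconds while Monte-Carlo bands (3σ throughout) stay tight enough to
be meaningful. Heterozygosity recovery is checked at 20,000 sites,
depth 50, error 0.5% (worst per-genotype error ≈ 0.6 percentage points
against truth, bound 2); the contingency null calibration uses 10,000
sites at α = 0.01. Exact ties in NJ's Q-criterion are compared with a
1e-12 tolerance before the lexicographic tie-break; permutation
p-values use the add-one estimator, which never returns 0. The
`percent` accounting helper rounds half away from zero at the precision
the caller requests and treats a zero denominator as an error.

## Known limitations

The contingency filter cannot retain a site whose variant fraction is
identical in every genotype (e.g. a locus where all genotypes are
duplex heterozygotes), a property inherited from the test's definition.
The HRM flank rule requires the full 18 polymorphism-free bases on both
sides *within the contig*, so SNPs near contig ends are ineligible even
if the true genomic neighborhood is clean. Genotype classification is
threshold-based, not model-based; a Bayesian dosage caller is out of
scope by design. VCF INFO floats are single precision, so p-values
below ~1e-38 read back as 0 from exported files (in-memory results are
double precision).
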