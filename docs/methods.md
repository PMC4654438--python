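# Methods

## Scope and data model

`locuspop` analyses biallelic SNVs in a contiguous genomic region for a
panel of diploid individuals organised in a two-level hierarchy
(population nested in ancestral group). Multi-allelic records are
dropped rather than split: the divergence, F_ST and two-locus LD
formulas used throughout are biallelic, and splitting would double-count
chromosomes. Indels are out of scope. Coordinates are 1-based inclusive
at every interface (VCF convention); any 0-based arithmetic is internal
to the I/O layer. Strand is ignored and alleles are taken as written.

Missing genotypes are tolerated everywhere and handled by per-locus
complete-case analysis within whatever sample scope is being computed —
each statistic records the chromosome count n it actually used. Nothing
is imputed. Removal of related individuals is an explicit exclusion-list
input, not a kinship computation.

Functional categories (upstream / intron / UTR / synonymous /
non-synonymous / intergenic / downstream) are inputs: either an
annotation table keyed by variant id, or interval assignment against a
gene model in which coding consequence is itself an input column. The
package never predicts consequence from transcript sequence.

## Diversity statistics

* **Frequencies and heterozygosity.** Per scope, x₂ = alt copies /
  complete-case chromosomes. Heterozygosity is *expected*
  heterozygosity with the small-sample correction,
  h = n/(n−1)(1 − x₁² − x₂²) — the only definition consistent with
  frequency-level inputs; observed genotype heterozygosity is used only
  inside the F_ST estimator where it is required.
* **Watterson-style θ̂** = K/(aₙL). n is *chromosomes*: with 1,074
  diploids, aₙ uses n = 2,148. This is normative in the package; using
  individuals instead fails to reproduce the per-class reference values
  the test suite checks. For synonymous and non-synonymous subsets the
  full coding length L is used as the denominator for both (no
  site-class length partition is attempted — densities are then
  comparable between the two classes and match the reference table
  convention).
* **SNP density** is reported as the round(L/K) denominator of
  "1 SNP per N bp"; K = 0 renders as 0 (undefined).
* **π** sums n/(n−1)·2x₁x₂ per site, divided by L. Sites with fewer
  than 2 complete-case chromosomes contribute nothing.
* **Divergence** d = 1 − [√(x₁y₁) + √(x₂y₂)], clipped to [0,1] against
  float rounding; symmetric, zero iff the spectra coincide.

## Differentiation

Per-locus F_ST is the Weir–Cockerham (1984) θ from per-group diploid
counts, allele frequencies and observed heterozygote frequencies,
decomposed into components a (among groups), b (among individuals
within groups), c (within individuals). Choices that matter:

* Negative component estimates are retained in all arithmetic and
  reported as-is; displays may floor at zero but computation never does.
* Loci monomorphic in scope have undefined θ (NaN) and are excluded
  from medians and multilocus sums.
* Multilocus F_ST is the ratio of sums Σa/Σ(a+b+c); the simple mean of
  per-locus ratios is also reported where per-category averages are
  wanted.
* The within-population statistic reported alongside the among-group
  median is the F_IS-style ratio b/(b+c), labeled `fis`. This is an
  interpretation: the reference analyses report a "within-population
  F_ST" whose exact estimator is not documented.
* Permutation significance permutes individuals between units; p-values
  use (exceedances+1)/(n+1), so p ∈ (0,1] and is never exactly zero. A
  seed is mandatory whenever permutations are requested.

AMOVA is the three-level allele-frequency (gene-copy indicator) variance
partition. Sums of squares reduce to functions of per-population
complete-case allele counts; variance components are computed per locus
from that locus's own copy counts and summed, which coincides with the
classical joint decomposition under complete data and degrades
gracefully under missingness. With exactly one population per group the
middle stratum has zero degrees of freedom and the design collapses to
two levels (σ²_b ≡ 0). Permutation schemes follow the index being
tested: whole populations among groups for Φ_CT, individuals among
populations within their group for Φ_SC, individuals among all
populations for Φ_ST. Only the allele-frequency AMOVA is implemented;
haplotype-distance AMOVA is out of scope.

## LD, tags, surrogates

r² is the squared correlation of allelic indicators on haplotypes.
Phased input uses direct haplotype counts (algebraically identical to
squared Pearson correlation of the indicator vectors); unphased input
estimates the four haplotype frequencies by EM over the
double-heterozygote ambiguity (start at linkage equilibrium, stop when
no frequency moves more than 1e-8 or after 1000 iterations;
non-convergence is flagged and the last iterate returned). The EM
solution equals the exact two-locus ML — verified against a dense
likelihood grid — but at weakly informative pairs (low r², mid MAF,
many double heterozygotes) even the exact ML can sit a few percent from
the phased-count value at n = 200; agreement claims about EM are
therefore statements about the mean over pairs, not pointwise bounds.

LD is always computed within one ancestral group at a time (group LD
structures differ too much for pooled r² to be meaningful). The MAF ≥
0.05 filter applies to all variants entering the pair set except index
SNPs, which are exempt (a rare index variant still deserves a surrogate
search; its surrogates must pass the filter).

Tag selection is greedy binning: repeatedly pick the variant covering
the most untagged variants at r² ≥ 0.8, bin it with its cover, remove,
repeat; ties break by coverage, then higher MAF, then lower position,
making output deterministic. No maximum bin-span constraint is applied.
Greedy is a heuristic: on sparse realistic instances it almost always
matches the exhaustive minimum (the suite checks ≥ 90% parity on
8-variant instances subsampled from simulated locus LD), but on dense
random graphs parity drops — this is a property of greedy dominating
sets, not of the implementation.

Surrogates of an index SNP are variants at r² ≥ 0.6 within 200 kb
(1-based inclusive distance) with in-scope MAF ≥ 0.05, sorted by
descending r². All three thresholds are configurable.

## Category comparison

Each variant is one observation. Variants monomorphic in a scope
contribute MAF 0 rather than being dropped, so a class absent from a
group drags that group's class average toward zero — which is the
signal of interest. The two-group test is Welch's unequal-variance
two-tailed t-test with Welch–Satterthwaite degrees of freedom
(category variances differ by construction, so the pooled-variance
variant would be wrong); the degenerate zero-variance-equal-means case
returns t = 0, p = 1. Raw p-values are reported; no multiple-testing
correction is applied. Cross-group similarity is the squared Pearson
correlation of paired per-variant values (≥ 3 complete pairs, positive
variance required).

## Synthetic data generator

The generator is a Balding–Nichols hierarchy chosen over coalescent
simulation because it parameterizes F_ST directly — the quantity the
estimators must recover — and runs at desk scale. Per variant: an
ancestral frequency p is drawn; each group draws from
Beta(p(1−F_g)/F_g, (1−p)(1−F_g)/F_g); each population repeats the draw
around its group frequency with the within-group F_p; individuals are
Hardy–Weinberg binomial, phased by construction. F = 0 is the exact
degenerate case (frequencies copied through). One seeded generator
drives everything; identical configs produce byte-identical output
files, and every file records the seed.

Defaults emulate the reference panel this pipeline is shaped around:
14 populations in 4 ancestral groups totalling 1,074 diploids
(group sizes 233/378/177/286), 1,627 variants over a 111,716 bp region
holding a low-LD gene and a high-LD gene, category fractions matching
the observed 903/72/46/26 class split, F between groups 0.10 (the
genome-wide autosomal benchmark), F between populations within groups
0.01. The ancestral MAF law is uniform on [0.01, 0.5] with a 30% point
mass of rare variants (uniform on [0.001, 0.05]) emulating the
rare-variant excess of sequencing panels.

Two features of real data are deliberately stylised:

* **LD** is injected by founder-mosaic copying, not recombination
  modelling: inside a configured block every chromosome of an ancestral
  group becomes a copy of one of a small founder set (default 3 per
  group) drawn from that group's own haplotypes. This produces the
  target contrast — high within-block r², independence elsewhere — and
  founders are shared across a group's populations, as ancient
  haplotypes in a recombination-free region are. Two side effects are
  accepted and should be kept in mind when reading simulated reports:
  founder sampling adds frequency dispersion at block loci, so block
  loci show *elevated* differentiation relative to the nominal F (as
  real low-recombination regions do), and r² decays with founder count
  rather than with distance.
* **Functional categories** are labels matched to realized MAF bands
  (non-synonymous from the ≤ 0.02 tail, synonymous ≤ 0.10 — the
  selection signature is planted, not evolved), then placed at
  positions consistent with the gene layout. There is no mutation
  model, no demography, no sequence content.

Consequently, passing tests demonstrate estimator correctness and
pipeline integrity under known truth; they do not validate coalescent
genealogical detail, LD decay with distance, or site-frequency-spectrum
shape. One cross-check that does need a neutral spectrum — the
expected agreement of θ̂ and π — is run against coalescent simulations
(msprime) in the test suite, because under the generator's uniform
ancestral spectrum that identity does not hold and should not be
asserted.

## Run scale and numerics

* Permutation count defaults to 10,000 for published-style reports; the
  bundled acceptance script and test suite run 200–1,000 permutations
  and 50–1,627-variant simulations, sizes chosen so the whole suite
  replays in minutes on one core while keeping Monte-Carlo error well
  inside the asserted tolerances (e.g. ±0.015 on F recovery at 1,000
  loci × 400 diploids, calibrated from pilot replicate spread).
* EM tolerance 1e-8 / 1000 iterations; divergence and r² clipped to
  their theoretical ranges against float rounding; medians over defined
  (non-NaN) loci only.
* Known limitations: no haplotype-distance AMOVA, no Gabriel block
  definition, no hotspot inference, no consequence prediction, no
  regulatory-annotation retrieval (regulatory columns pass through the
  surrogate report untouched), no plotting beyond TSV export of the
  plotted quantities.
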