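# Methods

`poolpopgen` implements the downstream analysis of a pooled amplicon
re-sequencing study of abiotic stress-responsive (candidate) versus
background (reference) genes in the wild tomato *Solanum chilense*, with
*S. ochranthum* as outgroup. The pipeline starts from position-level read
count tables (one row per reference position with depth and per-base
counts, as produced from pileups) and ends with gene-class, network and
SNP-type comparisons. A synthetic-data generator reproduces the statistical
structure of the study design so every estimator can be validated against
known truth.

## Data model and filtering

Coordinates are 1-based closed intervals (pileup convention). Per-position
quality is represented as a precomputed boolean flag — the upstream pileup
processing, not this package, judges base/mapping quality — so the masking
stage only applies two rules:

* depth below `min_depth` (default **2000** reads) → `low_depth`;
* quality flag set → `low_quality`.

Masking is a state, not a deletion: downstream windows need to count masked
neighbours. Thresholds are inclusive on the keep side (depth exactly 2000
passes). A passing site is called a SNP when the second most frequent base
reaches `maf_min` (default **1%**) of the four base counts; rarer bases are
treated as sequencing errors, and a fraction of exactly 1% is kept. Ties
for the minor allele are broken by count, then alphabetically, for
determinism. Multi-allelic sites are kept, represented by their top two
bases, and flagged; indels are assumed removed upstream (the table format
cannot represent them). The 1% rule is applied per population table.

## Site classification and Nei–Gojobori site counting

SNPs in coding sequence are classified by translating the reference codon
and the codon with the variant base substituted (the allele differing from
the reference; strand-aware via reverse complement). Stop codons are
treated as a 21st residue state: stop gain/loss is nonsynonymous,
stop-to-stop synonymous. Two SNPs in one codon are classified independently
against the reference background — a documented simplification.

Denominators for π_s, π_a, K_s, K_a use unweighted (equal-rate)
Nei–Gojobori counting: position *k* of a codon contributes
*f*\_syn = (synonymous single-base changes at *k*)/3 to L_syn and
1 − *f*\_syn to L_nonsyn. Codons touching any masked position are excluded
entirely, and numerators are restricted to the same sites, keeping both
sides of every per-site rate consistent. The counting scheme is isolated
behind one operation so a weighted variant could be swapped in.

## Diversity, divergence, Tajima's D, F_ST

Allele frequencies are plug-in read fractions. The sample size in every
small-sample correction is the pool chromosome count *n* (50 = 25 diploids
per population), never the read depth: reads resample the same *n*
chromosomes, and at depths ≥ 2000 read-sampling noise is second order.
Pool-seq-specific estimators (PoPoolation-style corrections) are out of
scope.

* Per-site heterozygosity: *h* = *n*/(*n*−1) · (1 − Σ_b p_b²).
* π_class = Σ *h* over SNPs of that class ÷ L_class; monomorphic sites
  contribute zero to the numerator and their weight to the denominator.
* Watterson: Θ_W = S / (a₁(*n*) · L), a₁(*n*) = Σ_{i<n} 1/i.
* Tajima's D uses the standard variance normalisation (constants a₁, a₂,
  b₁, b₂, c₁, c₂, e₁, e₂); at S = 0 the statistic is reported missing, not
  zero, so averages run over defined values only.
* Divergence K is the raw per-site proportion 1 − (read fraction of the
  outgroup base), no multiple-hit correction — divergence to
  *S. ochranthum* is modest and the simpler estimand is transparent. For
  the synonymous/nonsynonymous split, a diverged CDS site is assigned the
  class of substituting the most frequent non-outgroup base into the
  reference codon. Outgroup-N sites leave both numerator and denominator.
* F_ST is Hudson's 1 − H_w/H_b over SNP sites shared (unmasked) between the
  two populations, with H_w the mean of the two within-population
  heterozygosities and H_b = 1 − Σ_b p_{A,b} p_{B,b}. Values are clamped to
  [0, 1]; the raw value (slightly negative for identical frequency pairs,
  −1/(*n*−1) at p = 0.5) is retained for audit. The estimator sits behind
  one function so a Weir–Cockerham variant could replace it.

## SNP-neighbourhood windows

"40-bp windows around each SNP" is interpreted as 20 usable positions on
each side with the focal site excluded, making the 40 exact and preventing
a SNP's own heterozygosity from dominating its neighbourhood (`half_width`
is a parameter). A window is excluded when more than `max_masked` (default
3) positions are masked, or when the focal SNP is a species-wide fixed
difference to the outgroup — defined as the outgroup base falling below the
MAF threshold in **every** assessable population — since such sites predate
the within-species history. The focal position is never counted among the
masked (it passed masking to be called). Edge-truncated windows are kept
with the denominator reduced and flagged, allowing a drop policy downstream.

## Rank-sum comparisons

The Mann–Whitney U test is implemented in-package (two-sided only). For
tie-free samples with n₁+n₂ ≤ 12, p is exact by enumerating all
C(n₁+n₂, n₁) labelings. Otherwise a normal approximation is used with tie
correction, continuity correction, and — on tie-free samples — an Edgeworth
term for the U distribution's negative excess kurtosis,
κ₄ = −n₁n₂(N+1)(n₁²+n₂²+n₁n₂+n₁+n₂)/120 (verified against exact
enumeration over a grid of sample sizes). The correction brings exact and
approximate p within 0.003 for min(n₁,n₂) ≥ 3 at the crossover size; splits
with a smaller side always take the exact path. No multiple-testing
correction is applied by default (raw 0.05/0.001 significance tiers are
reported); a Benjamini–Hochberg step would be a thin addition.

Species-level comparisons default to pooling gene × population values as
observations (`mode="pooled"`); averaging per gene over populations first
(`mode="mean"`) and per-population comparisons (`mode="per-population"`)
are also provided, since the choice of unit is a genuine ambiguity. The
regulatory-vs-functional comparison runs over candidate genes only, with
the single sensory gene excluded. Network strata (AREB1: *dhn1*, *le25*,
*pLC30-15*, *TAS14*, *TPP*; JERF1: *LTP*, *pLC30-15*; each with its
regulator) are compared against the reference genes.

## Synthetic data generator

The generator defines the validation conditions:

* **Design**: 23 populations (groups NG 2, CG 13, SLG 4, SHG 4, using the
  study's LA accession ids), 50 alleles per pool, 16 candidate genes (1
  sensory, 5 regulatory, 10 functional, with the two networks above) plus
  14 reference genes. Only GBSSI is a published reference-gene id; the
  other thirteen (`ref01`..`ref13`) are synthetic stand-ins for unnamed
  single-copy cDNA markers. Loci are 1–5 kb with flank/CDS/intron
  architecture drawn per gene; both strands occur.
* **Haplotypes**: neutral infinite sites. S ~ Poisson(θ·a₁(n)) per locus;
  derived-allele counts follow P(i) ∝ 1/i; carriers are uniform without
  replacement. Optional per-site and per-base mutation weights let the
  generator plant class-specific effects (e.g. a 3× nonsynonymous-θ
  elevation in candidate genes) without touching the estimators.
* **Defaults** (the study reports none of these, so they were fixed once to
  field-plausible values and not revisited): θ = 0.01/site — typical silent
  diversity for an outcrossing wild tomato; mean depth 4000 — the design
  requires ≥ 2000×, and Poisson(2000) would put ~half of all sites below
  the threshold; per-read error 0.001 (post-quality-filter Illumina);
  quality-flag rate 0.002; outgroup divergence 0.03/site, of the order
  implied by a ~5.6 My split. Depth is Poisson so the depth mask is
  exercised naturally.
* **Pool sequencing**: per site, depth ~ Poisson(mean); each read draws a
  uniform haplotype's base and miscalls to a uniform different base with
  the error probability. An `exact` mode bypasses read sampling (counts
  exactly proportional to pool frequencies) for exact-recovery tests.
* **Truth records** carry per-locus S, segregating positions, derived
  counts and the direct haplotype π for oracle tests.

### What the generator does and does not emulate

It reproduces the marginal site-frequency spectrum, pool read-count noise,
depth variation, quality masking and outgroup divergence — the features the
estimators consume. It does **not** generate coalescent-faithful linkage
between sites (sites are exchangeable given S), recombination, selection,
migration or demography, and the outgroup has no polymorphism. Passing
tests therefore validate estimator correctness and calibration under
neutral SFS-correct input, not robustness to linked selection or population
structure. One measurable consequence: Tajima's D computed on these samples
has mean ≈ 0 but variance ≈ 0.15 rather than ≈ 1, because the e₂·S(S−1)
term of the variance normalisation models between-site coalescent
covariance that independent sites lack. The approximate standard-normality
of the D normalisation is therefore checked against genealogy-faithful
coalescent samples (msprime, test-only dependency), where the variance
falls in the expected band while the mean shows the well-known small
negative bias.

## Problem sizes used in validation

The calibration runs use 1000 neutral replicates (n = 50, θ = 10 per locus)
for the mean of D; 50 loci at depth 10⁵ for pooled-vs-truth recovery; 400
coalescent replicates for the D-variance band; exhaustive enumeration for
codon counts and small-sample rank-sum exactness; 1000 null replicates for
type-I calibration; and 10 full-scale study replicates (23 populations × 30
genes) for recovery of the planted 3× nonsynonymous elevation.

## Known limitations

* Linkage, recombination and demography are not simulated (above).
* The exact F_ST estimator of the original analysis is not identifiable
  from its description; Hudson's form is comparable in structure but not
  guaranteed numerically identical.
* Whether the original windows include the focal SNP, and whether its π
  denominators count masked sites, is unstated; this package excludes the
  focal site and masked sites, with parameters to explore alternatives.
* Absolute π_s/π_a levels depend on the site-counting scheme; with the
  counting scheme unpublished, levels are comparable structurally, not
  numerically.
* Multi-allelic sites are kept as their top two bases; S counts a site once
  regardless of multi-allelism.
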