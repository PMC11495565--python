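# Methods

## Data model

All analyses run on two structures.  A `SitePanel` is an ordered list of
biallelic SNPs (chromosome, 1-based position, reference and derived allele,
transversion flag); sites are kept sorted with numeric-aware chromosome
order and unique positions.  An `AlleleCountMatrix` stores, per unit and
site, the derived-allele count and the number of called alleles; missingness
is encoded as `called_total = 0`, so pooled frequencies
`p̂ = Σ derived / Σ total` need no sentinel handling.  Diploid individuals
contribute totals of 2, pseudohaploid units totals of 1, and "pooled" units
(population-level count columns, used mainly in tests) are unconstrained.
The same frequency machinery therefore serves diploid moderns, haploidized
ancients and mixtures of both.

## Pseudohaploid calling

Low-coverage ancient samples are represented by one randomly chosen read
allele per site: reads below the base-quality floor (default Q30) or
carrying a non-panel allele are discarded, one survivor is drawn uniformly,
and sites without survivors stay missing.  This yields an unbiased (if
noisy) estimate of the sample's allele frequency at every depth, avoiding
the systematic heterozygote loss of diploid calling at low coverage.  The
pileup dialect carries no per-read mapping quality, so MAPQ filtering is
assumed done upstream when the pileup is generated (as `samtools mpileup -q`
does); only the base-quality floor is applied here.

## Ascertainment filters

`ascertain_panel` applies, in order: per-sample missingness (drop samples
above 10% missing), a biallelic validity check, per-site missingness (5%),
minor allele frequency (≥ 0.05 on non-missing alleles), a two-sided exact
Hardy–Weinberg test (p ≥ 0.001, computed on the ascertainment cohort's
diploid genotypes by summing all heterozygote configurations no more
probable than the observed one), and finally a spacing thin.  The thin is
keep-first greedy: scanning by position, a site is kept only if it lies at
least 5 bp beyond the previously kept site.  "Remove close pairs" is
ambiguous between dropping one or both members; keep-first maximizes
retained sites and is deterministic, so that reading the pipeline's output
back through the pipeline is a fixed point (tested).  Sample filtering
precedes site filtering, matching common PLINK semantics.

## f-statistics and uncertainty

f3, f4 and D are computed from pooled population frequencies under the
complete-case rule: a site enters a statistic only when every involved
population has at least one called allele.  f3 is the uncorrected form
(no heterozygosity correction), which is well-defined for single
pseudohaploid genomes whose site frequencies are 0 or 1 — the price is that
f3 values are shifted by sampling noise, which cancels in the contrasts the
pipeline actually reports (pairwise 1 − f3 comparisons within one panel).
D uses the frequency (Patterson) form with the heterozygosity-product
denominator; with the outgroup in slot 1, negative D means excess affinity
of the slot-2 population to slot 3.  Sites where every population is fixed
contribute zero to numerator and denominator and are not special-cased.

Standard errors use a weighted delete-one block jackknife over contiguous
blocks of 1 Mb (configurable).  Blocks are `(chromosome, floor(pos / B))`;
weights are sites-per-block; the variance is Busing's weighted-jackknife
form applied to the ratio-of-sums estimator.  For the f4-ratio, the ratio
itself is jackknifed (leave-one-block-out ratio) rather than propagating
numerator and denominator errors, since the two share most of their
sampling noise; the denominator's own Z is checked and a warning is issued
below |Z| = 3.  Calibration is tested empirically: across 200 independent
replicates of a symmetric four-population demography (100k sites, 50
blocks), the mean jackknife SE falls within [0.7, 1.4]× the empirical SD
and ≤ 2% of |Z| scores exceed 3.

## Ordination

`pca_fit` is a smartpca-style PCA of diploid genotypes: missing calls are
imputed with the site mean, columns centered and scaled by
`sqrt(p̃(1−p̃))` with `p̃ = (1 + Σg) / (2 + 2n_called)` (the pseudocount
keeps near-fixed sites finite), then an SVD.  Monomorphic sites are dropped.
`pca_project` places additional samples — typically pseudohaploid ancients,
whose calls are doubled onto the diploid dosage scale — by least squares on
their non-missing sites only; missing sites are excluded from the normal
equations rather than imputed, which avoids the shrinkage toward the origin
that mean imputation causes.  Component signs are fixed by making each
component's largest-magnitude loading positive, so coordinates are
reproducible across sample orderings.

`dpca` ordinates whole populations: with a fixed outgroup in slot 1 and
each focal population in slot 2, it computes D(outgroup, focal; C, D) for
every unordered pair {C, D} over the population set (canonical
lexicographic orientation, pairs containing the focal population included —
they are still well-defined statistics), centers columns, and takes an SVD.
This layout yields a complete rectangular matrix with a fixed column space,
which is the property the downstream PCA needs; the point estimates alone
determine the ordination, so no jackknife is run per cell.

## Diversity contrasts

Within-group diversity uses pairwise `1 − f3(outgroup; g_i, g_j)` with each
genome as a single unit, transversions only by default.  Pairs overlapping
on fewer than 5,000 sites (configurable) are reported missing rather than
estimated — with fewer sites the f3 noise dominates group contrasts.  Group
differences are tested with Kruskal–Wallis (tie-corrected H, chi-square
reference) and pairwise two-sided Wilcoxon rank-sum tests: exact
enumeration when both groups have n ≤ 10 and no ties, otherwise the
tie-corrected normal approximation.  Raw p-values are reported with a
Bonferroni column alongside.  Both tests are thin wrappers over
scipy.stats with the degenerate cases (all values identical) handled
explicitly; the test suite checks them against full-enumeration oracles.

## Sexing and consensus

The Rx statistic compares X-chromosome read density to each autosome:
`ratio_i = (reads_X/len_X)/(reads_i/len_i)`, Rx is the mean ratio and a
normal 95% CI is taken over autosomes.  Calls are conservative: XX only if
the whole CI exceeds 0.8, XY only if it lies below 0.6, otherwise
indeterminate.  These thresholds follow the original Rx convention and are
exposed as parameters, since species-specific re-optimized cutoffs are not
generally available.  Zero-read chromosomes are dropped with a warning; at
least two usable autosomes are required.

The mitochondrial consensus is a per-position threshold rule on base-count
columns built with a Q40 quality floor: coverage below 10× gives 'N',
otherwise the most frequent base is called when its share is ≥ 2/3.  The
boundary is inclusive (8 of 12 calls the base) and argmax ties give 'N'.
Reference-bias-aware iterative assembly is out of scope; only the consensus
thresholding is implemented.

## The synthetic-data generator

`simdata` simulates derived-allele frequencies down a rooted tree under the
Balding–Nichols model: given parent frequency p and branch drift F, the
child is `Beta(p(1−F)/F, (1−p)(1−F)/F)`, so `E = p` and `Var = F·p(1−p)`;
F = 0 copies the parent and fixed frequencies stay fixed.  Admixed nodes
take `α·p_A + (1−α)·p_B` before optional residual drift.  Root frequencies
are Uniform(0.05, 0.95) by default, mirroring a common-variant ascertained
panel (MAF ≥ 0.05).  Sites are placed uniformly over a configurable number
of synthetic chromosomes (default 26, sheep-like) so megabase jackknife
blocks are meaningful; two-thirds of sites are transition-class by default
(ts/tv ≈ 2:1, typical for mammalian genomes and configurable, since no
single empirical value fits all panels).

Sampling draws diploid genotypes Binomial(2, p), pseudohaploid calls
Bernoulli(p), and read-level pileups with Poisson depth, reads drawn from
the individual's two alleles, and Q37 base qualities with a 10% low-quality
(Q20) fraction to exercise quality filters.  Damage is applied to pileups
as per-read C→T and G→A flips with probability δ at transition-class sites
only, emulating postmortem deamination closely enough that transversion-only
analyses are provably immune.  Real aDNA features the generator does *not*
model: position-in-read damage gradients, fragment-length variation,
mapping bias, reference bias, contamination, and linkage between nearby
sites.  Passing tests therefore demonstrate the estimators' correctness
under idealized sampling, not robustness to alignment artifacts.

## Study-scale choices

The canned experiments in `ovipop.workflows` fix the simulation conditions
used throughout the tests and drivers: the five-population Baltic admixture
model uses α = 0.70 with per-branch drift between 0.01 and 0.05, 200,000
sites, eight pseudohaploid ancients per population at 20% missingness and
four diploid outgroup genomes — enough that the f4-ratio's jackknife SE is
about 1.5 percentage points.  Calibration replicates use 100,000 sites on
fifty 1 Mb chromosomes (50 blocks) and 200 replicates; the damage contrast
uses 150,000 sites, δ = 0.15, and six ancients at 2× depth.  The numbered
analysis drivers run a smaller 40,000-site cohort, which keeps the whole
pipeline's runtime in seconds while leaving every qualitative signal
(affinity D signs, diversity ordering, admixture direction) clearly
resolved; its f4-ratio has a correspondingly wide SE, which the driver
prints alongside the estimate.

## Known limitations

- The frequency-based D differs subtly from read-count ABBA-BABA
  implementations; signs and Z-score semantics are convention-invariant,
  absolute values need not match across tools.
- Vanilla f3 on pseudohaploid singletons is upward-noisy; only contrasts
  within a panel are interpretable, not absolute f3 levels.
- The simulator has no recombination map or coalescent structure, so
  jackknife blocks are independent by construction; real data's residual
  long-range linkage can make jackknife SEs slightly anti-conservative.
- EIGENSTRAT output codes pseudohaploid calls homozygous (0/2); round-trips
  need the caller-supplied ploidy map to restore haploid totals.
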