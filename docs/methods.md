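# Methods

This note documents the models and procedures implemented in `sweepcontrast`,
the defaults and why they were chosen, what the synthetic data emulate (and do
not), and the numerical conventions that matter for reproducing results.

## Input model and filtering

The pipeline consumes biallelic SNPs only: records with more than one ALT
allele or with REF/ALT longer than one base are dropped on ingest. Two sample
payloads are supported. *Individuals* carry genotypes plus a genotype quality
(GQ); calls with GQ below 20 are set missing ("minimum of 20" is inclusive:
GQ = 20 passes). *Pools* carry ref/alt allele depths and a total depth DP;
sites with DP below 4 are set missing. Filtering is idempotent and never
fails. A generic site-level filter hook is exposed (default pass-through) for
upstream caller-specific site filters, which vary between studies and are not
standardised here.

Per-breed reference-allele frequency is the reference-allele count over all
called alleles of the breed. Males are hemizygous on the X chromosome and
contribute one allele there, whether their call is written haploid or
(redundantly) diploid. A pool contributes one diploid pseudo-observation:
2 · refDepth/DP reference alleles out of 2. No binomial correction for finite
pool depth is applied — the frequency estimate is the plug-in ratio — because
the depths involved (≥ 4) make the correction second-order for windowed
averages, and any correction would need a pool-size model the input does not
carry.

## In-silico pooling

Group (pool) frequency is the *unweighted* arithmetic mean over member breeds
with a record, so breeds with many sequenced animals do not dominate the
contrast. A locus is excluded from both pools when, in either group, strictly
fewer than half of the member breeds have a record; a breed "has a record"
when its frequency cell is non-missing after filtering. The boundary is
strict: exactly 50% of breeds with records retains the locus.

## Windowed scan

Windows are 100 kb with 80% overlap (20 kb step), 0-based half-open, starting
at 0 on every chromosome. Trailing partial windows are dropped so all windows
have equal size; unequal windows would make the Z-scores incomparable.
Windows with fewer than 10 contributing loci (configurable) are missing.

Expected heterozygosity Hexp = 2p(1−p) uses the minipig-pool frequency.
Window means are Z-normalised with the mean and *population* (n-denominator)
standard deviation of all non-missing windows, autosomes and the X
chromosome separately — the X has its own diversity level and its own sweep
backdrop, so a joint normalisation would mis-calibrate both partitions.

Outlier regions are called by seed-and-extend: a window at or beyond the
seed threshold (default: the empirical 1% quantile of the window values)
starts a region, which grows over contiguous windows at or beyond the
extension threshold (5% quantile); overlapping window spans merge. The
classical fixed thresholds −2.34/−1.64 can be supplied instead of quantiles —
for a near-Gaussian Z track the two parameterisations coincide. Hexp uses the
lower tail, FST the upper.

The per-locus fixation index between the two pools uses the weighted mean
frequency p̄, the average group size n̄, and is undefined (missing) when p̄ is
0 or 1. Group sizes are the per-locus numbers of breeds with a record.

Final sweep regions are the union of heterozygosity and CLR regions,
restricted to those overlapping an FST region by at least 1 bp, filtered to a
minimum width of 200 kb *before* padding, then padded by 0.5 Mb per side
(clipped at chromosome ends) and merged. Provenance labels (hexp/clr/fst)
are carried through merging.

## Composite likelihood ratio test

The CLR scan reimplements the classical star-approximation sweep model. At a
candidate sweep position, each of the n sampled lineages escapes the sweep
independently with probability p_e = 1 − exp(−α·d), where d is the physical
distance of the site to the candidate position and α is the sweep-strength
parameter (physical distance proxies recombination distance; no genetic map
is used). Non-escaped lineages coalesce into a single lineage whose allelic
state is exchangeable with the escaped ones; escaped lineages draw from the
genome-wide background spectrum, downsampled hypergeometrically to the
number of independent lineages. All site distributions are conditioned on
polymorphism because invariant sites are excluded from the data. The folded
spectrum (minor-allele counts) is the default since ancestral states are
unavailable; the unfolded variant is a flag.

The composite likelihood is maximised over 40 log-spaced α values spanning
sweep footprints (distance at which p_e = 1/2) from 10 kb to 10 Mb, and
LR = 2(ln CL_sweep − ln CL_background), clipped at zero. Numerics: site
probabilities are tabulated on 257 escape-probability bins (the p_e = 0 bin
is evaluated at 10⁻⁸ so the polymorphism conditioning has a well-defined
limit); sites beyond 3 Mb of a grid point are treated as fully escaped, which
makes their contribution cancel exactly between the two models — grid points
with no site in range therefore have LR = 0 identically. The scan requires a
constant sample size n across sites (the synthetic data guarantee this;
variable-n data should be projected or split beforehand). The grid step
defaults to 20 kb, matching the window step. Top-1% grid points (ties kept)
become CLR regions, each spanning half a grid step per side.

A parser for externally produced SweepFinder grid files feeds the same
downstream combination, so an external CLR run is interchangeable with the
internal scan.

## Phylogeny and group FST

Pairwise distance between individuals is 1 − IBS similarity, where per-locus
similarity is the shared-allele fraction (identical genotypes 1, homozygote
vs heterozygote 1/2, opposite homozygotes 0), averaged over
pairwise-complete loci. Neighbor joining is the standard Saitou–Nei
agglomeration with two determinism conventions: tied Q minima resolve to the
lowest-index pair, and negative branch lengths are clamped to zero with the
deficit moved to the sister branch. Output is Newick; a square PHYLIP
distance-matrix writer is provided for interoperability.

Genome-wide group FST averages the per-locus index over loci whose allele
call-rate reaches 90% in both groups (call-rate is called alleles over the
per-breed maximum observed). The standard error uses a leave-one-chromosome-
out jackknife, which is robust to the strong local correlation of FST along
the genome; a naive per-locus SE is available by flag and is smaller than
honest.

## GO over-representation

For every GO term with at least one gene overlapping a sweep region (any
overlap ≥ 1 bp counts), a 2×2 table over the annotated gene universe gives a
one-sided (over-representation) Fisher exact p-value — the hypergeometric
upper tail — and fold enrichment FE = a/[(a+b)(a+c)/N]. The universe is all
genes in the supplied annotation.

Because genes cluster along chromosomes, raw Fisher p-values are
anti-conservative; significance is calibrated positionally: the genome is
treated as a circle of concatenated chromosomes (declared order), and each of
B = 5000 replicates shifts the *whole* region set by one uniform offset in
[1, genome length], wrapping around. Shifting on the circle preserves every
region's size and the region count exactly (a wrapped region is one region
split across the join); splitting at chromosome junctions instead would
shorten regions and bias the null. Genes are re-annotated against the
shifted set and per-term p-values recomputed. A term is significant when its
observed p lies strictly below the 5% quantile (type-7, linear interpolation)
of its permuted p-values; the empirical rank p-value
(1 + #{perm ≤ obs})/(B + 1) is reported alongside, since both readings of
"empirical p" appear in practice.

## X-linked haplotype QTL

Chip genotypes in the sweep interval are filtered in order: individuals with
more than 90% missing genotypes, then SNPs with call rate strictly below 90%
or minor allele frequency strictly below 1% (boundaries pass). Diagnostic
("informative") markers are fixed within each founder group and fixed for
different alleles between groups — one heterozygous founder disqualifies a
marker. F2 animals with a unanimous diagnostic-marker pattern map to three
classes: (1) homozygous females / hemizygous males carrying the large-pig
haplotype, (2) heterozygous females, (3) hemizygous-minipig males.
Discordant patterns are left unassigned rather than majority-voted: the
design assumes no recombination inside the sweep, so discordance flags a
genotyping error or a recombinant, not a class.

The size model is ordinary least squares on the full fixed-effects model
(breed of founder dam, sex, age, age², haplotype nested in sex, and the
breed×sex, breed×age, breed×age², breed×haplotype(sex), age×haplotype(sex)
interactions; age is centred for conditioning). Backward elimination removes,
at each step, the removable term with the largest partial-F p-value above
α = 0.05; a term contained in a retained interaction (including age under
age²) is never removable, so protected main effects can remain with p > α —
the standard marginality convention. Ties break to the later term in the
declared order, making selection deterministic. A flag forces retention of
the focal haplotype(sex) term regardless of its p-value, for reporting
effect sizes of borderline traits. LS-means evaluate the fit at balanced
factor levels and covariate column means; pairwise contrasts are unadjusted
t-tests (LSD). A single residual variance is fitted (no sex-specific
residuals, no random litter effects).

Under the null (no haplotype effect), total retention of haplotype(sex) is
noticeably above α because a spuriously significant containing interaction
protects it (≈ α + 1 − (1 − α)² ≈ 0.14); the α-level event is the term
surviving its own partial-F test, which is what the calibration test counts.

## Synthetic data

The generator produces the statistical structure the analysis assumes, not
sequence realism. Allele frequencies follow a two-layer Balding–Nichols
hierarchy: per locus an ancestral frequency π ~ Uniform(0.05, 0.95); a group
frequency p_g ~ Beta around π; breed frequencies Beta around p_g. The
concentrations are set so a breed's total marginal divergence from π is
F_bg = 0.10 of π(1−π) — the scale of differentiation among pig breed groups —
with half of it (configurable) carried by the group split, so breed groups
form clades in the IBS tree and group-level FST is non-trivial. Defaults: two
groups of five breeds, six individuals per breed, 18 autosomes plus X
totalling 540 Mb, 200 loci/Mb (enough for ~20 loci per 100 kb window so the
10-locus window threshold rarely triggers). Problem sizes were chosen so the
full scan, including the CLR stage, completes in well under a minute.

Sweeps are injected by deterministic frequency shrinkage: inside the region,
each target-group breed frequency moves toward fixation, p ← p(1−intensity)
(or symmetrically toward 1). This creates exactly the low-Hexp/high-FST/
skewed-SFS signature the summary statistics detect, without simulating
genealogies — the scan tests signatures, not coalescent histories. Defaults
inject six 1 Mb sweeps of intensity 0.9 on six autosomes.

Individual genotypes are binomial Hardy–Weinberg draws from breed
frequencies (haploid for males on X), written as VCF with GQ/AD/DP fields
above the filter thresholds by default so the ingest path is exercised; CLR
site counts are drawn the same way without materialising a VCF.

The F2 cross transmits X haplotypes by the Mendelian rules of the design
(founder dams homozygous large, sires hemizygous minipig; no recombination):
F1 females all heterozygous, F1 males hemizygous large; F2 females half
homozygous-large, half heterozygous; F2 males half large, half minipig.
Phenotypes are built on the slaughter-size scale (mean ≈ 65 cm) from founder
breed (+1 cm Duroc), sex (+1.5 cm males), a decelerating age trend over
166–439 days, a −3 cm effect in hemizygous-minipig males, and Gaussian
residuals of 1.5 cm. The residual scale is the one deliberate idealisation:
real slaughter-size traits retain residual scatter of several cm after
covariate adjustment, which would widen the QTL estimator's sampling error
accordingly; 1.5 cm makes estimator bias and coverage sharply testable at
n = 400. Passing tests therefore demonstrate correctness of the estimator
and the selection procedure, not the power achievable on field data.

What the generator does not emulate: linkage disequilibrium within breeds,
sequencing error, variable coverage, GO-term correlation structure (term
memberships are uniform draws), and recombination inside the X sweep.

## Truth comparison conventions

A truth interval counts as recovered when any combined region overlaps it by
≥ 1 bp. The false-positive genome fraction is the genome share covered by
combined regions overlapping *no* truth interval; the 0.5 Mb padding around
a recovered sweep is method behaviour, not a false call, so it is not counted
against the scan.
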