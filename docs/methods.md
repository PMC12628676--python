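# Methods

## Scope and model

`ecoassembly` infers, for every pair of microbial communities in one
habitat, which of five assembly processes best explains their turnover, and
aggregates those pairwise calls over a replicated lake-survey design.  The
inference rests on two null models:

**βMNTD / βNTI.**  βMNTD is the abundance-weighted mean cophenetic distance
from each taxon to its nearest relative in the partner community; shared
taxa contribute zero.  The null shuffles taxon labels across the tips of
the phylogeny — one permutation per replicate, applied to the pooled taxon
set (every OTU with non-zero counts anywhere in the analyzed table) and to
all pairs simultaneously — and βNTI is the observed value standardized by
the null mean and SD.  Because shared taxa stay shared under a consistent
relabeling, βNTI is driven entirely by *unshared* abundance: it asks
whether the taxa two communities do **not** share are closer relatives
(selection under similar conditions, βNTI < −2) or more distant relatives
(selection under different conditions, βNTI > +2) of the partner community
than random tips would be.  Pairs whose null SD is < 1e-12 (e.g. identical
communities) are flagged degenerate and labelled `undetermined`.

**Raup–Crick with Bray–Curtis.**  For each sample a set of null communities
is built by (i) drawing the sample's observed richness from the pool
without replacement with probability proportional to occupancy (fraction of
samples containing the taxon), (ii) seeding one read per drawn taxon and
distributing the remaining reads multinomially proportional to pooled
relative abundance restricted to the drawn taxa.  Replicate *r* of pair
(*k*, *m*) compares Bray–Curtis between null community *r* of *k* and null
community *r* of *m*; RC_Bray rescales the fraction of null values below
the observed one (ties, at 1e-12 tolerance, count half) to [−1, 1].

**Classification.**  βNTI < −2 → homogeneous selection; βNTI > +2 →
variable selection; otherwise RC_Bray > +0.95 → dispersal limitation,
RC_Bray < −0.95 → homogenizing dispersal, else drift.  All inequalities are
strict: βNTI of exactly ±2 is stochastic and RC_Bray of exactly ±0.95 is
drift.

**Prerequisite.**  βNTI is only meaningful when phylogenetic distance
proxies ecological similarity over short distances.  The package estimates
per-OTU environmental optima as scores on the first constrained CCA axis of
the abundant-taxa table (>1% relative abundance in ≥1 sample by default)
against the environmental variables, testing the axis by permuting
environment rows; if no axis is significant an abundance-weighted-mean
fallback is available, and the pipeline refuses (without `force`) to run
βNTI when no short-distance correlogram class is significantly positive.

**Mantel correlogram.**  Cophenetic distances are cut into 30 equal-width
classes.  Per class, the statistic is the Pearson correlation between
|Δoptimum| and the class indicator, negated so positive values mean
positive autocorrelation; p-values come from two-sided taxon-relabeling
permutations.  The progressive Bonferroni correction multiplies class *k*'s
p by *k*, and the `significant` flag follows the sequential correlogram
reading: evaluation stops at the first non-significant class.  The
sequential rule keeps the family-wise error of "any significant class" at
the nominal level of the first class (measured ≤5% across simulations);
flagging every corrected-significant class independently would inflate it
several-fold with 30 classes.

## Turnover partitioning

Within one habitat, pairs are categorized as intra-lake (same lake and
year), inter-lake same-year (spatial), inter-year same-lake (temporal), or
other (different lake **and** year; counted only in "all").  Within a
subset, pairs are grouped by unordered replicate combination (A-A, A-B,
B-B; an ordered mode distinguishing A-B from B-A — ordering samples by
lake, then year, then replicate — is available).  Process occurrences are
converted to percentages per combination type; the summary reports the
unweighted mean, SD (ddof = 1) and a normal-approximation 95% CI
(1.96·SD/√n_types) across types.  Differences between subsets are tested
per process with an exact two-sided permutation test on |mean difference|
of the per-type percentages (full enumeration up to 20 000 relabelings,
Monte-Carlo beyond; the observed statistic is always counted, so p > 0).

## Core microbiomes

Presence is strict `>` at the 0.1% detection level; membership requires
presence in ≥75% of units.  For the spatial core of a year the units are
lakes (a lake counts as "present" when any of its replicates that year
exceeds detection; a mean-across-replicates mode exists); for the temporal
core of a lake the units are years.  Cumulative core abundance is the mean
± SD across the relevant units of the summed relative abundance of
members.  Raising either threshold can only shrink a core.

## Synthetic study designs

The generator emulates the sampling design the package targets: lakes on a
sub-kilometre coordinate grid, sampled in repeated summer campaigns
(default years 2017/2019/2021/2023), two habitats, duplicate samples A/B;
defaults are 11 lakes × 4 years × 2 habitats × 2 replicates, a 300-OTU
regional pool and 7 690 reads per sample (matching a typical rarefaction
depth; the validation scenarios use 8 × 2 × 1 × 2 at 5 000 reads to stay
fast on one CPU).  Counts are multinomial draws from per-sample weight
vectors, so library sizes are exact and only sampling noise separates
replicates.

**Regional pool.**  The pool phylogeny is a two-level *radiation* tree:
n/5 clades of ~5 tips, each clade a tiny Yule subtree with short
exponential branches (mean 0.02), hanging from near-equal stems (1.0 ±10%).
Brownian niche optima (rate 1 per unit branch length, standardized to mean
0/SD 1) are therefore nearly constant within clades and independent between
clades — an explicit, strong form of niche conservatism.  A plain
single-level Yule simulator with i.i.d. exponential branch lengths is also
provided (and tested); it was not adopted for the pool because the βNTI
z-score is then bounded near −1.3 regardless of how strongly communities
are filtered: the null variance is dominated by a common clade-coverage
fluctuation, whose inverse coefficient of variation caps |z|.  Many small,
equally deep clades shrink that common fluctuation and give selection a
detectable signature at realistic design sizes.  Pool relative abundances
are lognormal (σ = 1.2).

**Scenarios.**  Per-sample weight vectors:

* *Variable / homogeneous selection* — Gaussian filter
  exp(−(opt−env)²/2σ²) with niche breadth σ = 0.3 on the standardized
  optimum scale; lake environments spread over ±1.5 (variable) or fixed at
  +1.0, one end of the regional niche spectrum (homogeneous — filtering
  toward the spectrum's *mean* selects taxa from every clade and produces
  no clustering).  The kernel damps neutral pool abundances
  (pool^0.3): under strong selection realized dominance reflects fitness
  under the filter rather than regional commonness.  Three further
  ingredients make selected communities exchange close relatives instead of
  sharing every taxon — a weak immigration floor (5·10⁻⁵ of the filter
  peak) that keeps maladapted taxa present as scattered singletons so the
  pooled taxon set spans the whole tree; lake-year lognormal dominance
  turnover within the fit set (σ = 0.3); and lake-year occupancy thinning
  (each pool member locally present with probability 0.5).  Replicates
  share the full lake-year state.
* *Dispersal limitation* — each lake hosts a private uniform-random 30%
  subset of the pool with a lake-specific lognormal founder/priority effect
  (σ = 2) on within-lake dominance, stable across years (colonization
  history).  Without the founder effect the occupancy-weighted Raup–Crick
  null reproduces private-subset turnover almost exactly and RC_Bray
  plateaus near +0.7.
* *Homogenizing dispersal* — every sample is a multinomial draw straight
  from the common pool; the skewed pool is what lets the null (which drops
  dominants with appreciable probability when matching richness) sit far
  above the observed dissimilarity.
* *Drift* — one bottleneck-and-regrow cycle per sample lineage at 20% of
  the library size.  Harsher drift (e.g. a 5% bottleneck iterated five
  times) produces divergence beyond the Raup–Crick null spread and is
  classified as dispersal limitation — a real property of the framework,
  not of the implementation — so the constants were chosen to represent
  demographic noise the null model can absorb.  Both constants are
  module-level and overridable.

With these defaults each scenario is recovered as the modal label of its
relevant comparison subset (inter-lake pairs for variable selection and
dispersal limitation, all pairs otherwise) in ≥2 of 3 seeds at the
validation design size; homogeneous selection is the tightest case, with
median βNTI around −2.

**What the generator does not emulate:** sequencing error, chimeras and
compositional artifacts; environmental covariance structure beyond one
gradient variable; uneven library sizes; missing replicates; taxonomic
annotation.  Passing recovery tests therefore demonstrates that the
inference machinery is calibrated and able to separate the five processes
when their signatures exist — not that any particular real dataset meets
the generator's assumptions.

## Numerical and design choices

* Shannon diversity uses natural logarithms.
* PERMANOVA is single-factor (the pipeline tests lake identity and year
  separately per habitat); p counts the observed statistic among the
  permutations, so it is never 0, and its floor is limited by label-partition
  collisions in small balanced designs.
* Group-dispersion distances are computed in full PCoA space with the
  imaginary-axis correction for negative eigenvalues (tiny negative squared
  distances clipped to 0); the permutation acts on the distances-to-centroid.
* Distance-decay significance is a two-sided Mantel-style permutation of
  sample identities; OLS slope/intercept/R² are reported alongside.  For a
  perfectly linear relation an order-reversing permutation ties |r| = 1, so
  the attainable p floor is (1 + #ties)/(n_perm + 1).
* Haversine distances use a 6 371 km sphere.
* Rarefaction is a single seeded multivariate-hypergeometric draw per
  sample; samples below depth are dropped and reported.
* The dataset-wide low-abundance OTU filter compares strictly `<`
  (an OTU exactly at threshold is retained); the per-sample abundant-taxa
  filter for CCA compares strictly `>`.
* All randomness flows through one master seed with CRC32-keyed named
  substreams (stage, sample id), making results independent of evaluation
  order and safe to parallelize.  Raup–Crick nulls are drawn per sample and
  reused across that sample's pairs, which guarantees RC_Bray symmetry and
  scales null construction with the number of samples rather than pairs.
* Default null/permutation counts are 999; validation runs use 199 to keep
  the full five-scenario recovery matrix within a few minutes on one CPU.

## Known limitations

* βNTI cannot detect homogeneous selection when the filter is so strict
  that unselected taxa never occur anywhere in the table: the tip-shuffle
  null only relabels observed taxa.  Real surveys escape this through
  habitat heterogeneity and rare immigrants; the generator models it with
  the immigration floor.
* RC_Bray inherits the usual sensitivity of Raup–Crick indices to the pool
  definition; the implementation pools all samples in the analyzed table,
  so habitats must be analyzed separately (the pipeline enforces this).
* The exact permutation test treats comparison types as exchangeable units;
  with few types (e.g. three) only coarse p-values are attainable.
* Multi-factor (sequential SS) PERMANOVA, PCNM/variation-partitioning and
  taxonomy-aware core summaries are out of scope.
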