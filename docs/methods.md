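# Methods

`topodissect` dissects the phylogenetic signal that individual loci carry
for a small set of competing species-tree resolutions. This note records
the models and procedures implemented, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical decisions a maintainer would want to know about.

## Gene-wise log-likelihood scores (GLS)

For each locus and each candidate topology the package computes the
log-likelihood of the locus' amino-acid alignment under that fixed
topology, summed over alignment columns. The per-column values come from
Felsenstein's pruning algorithm over a time-reversible 20-state model:

* **Substitution models.** GTR-family amino-acid models built from a
  symmetric exchangeability matrix `s` and stationary frequencies `π`:
  `Q_ij = s_ij π_j` (i≠j), diagonal set so rows sum to zero, rescaled so
  `−Σ_i π_i Q_ii = 1` (branch lengths in expected substitutions/site).
  LG, WAG and JTT are shipped as PAML-format data files (frozen by a
  checksum test) alongside the Poisson (equal-rates) model; `+F` replaces
  the matrix frequencies with observed ones, `+G4` adds discrete-gamma
  rate variation.
* **Transition probabilities.** `P(t) = exp(Qt)` evaluated through the
  symmetric similarity transform `B = diag(√π) Q diag(1/√π)`,
  diagonalized once per model; eigenvalues are clamped to ≤ 0 and
  probabilities to ≥ 0 against rounding. This is stable for any `t` and
  verified against `scipy.linalg.expm`.
* **Among-site rate variation.** Discrete gamma with 4 equal-weight
  categories represented by their category means (not medians), the
  common default of mainstream ML engines; category likelihoods are
  mixed with equal weights at the site level.
* **Missing data.** Gaps, ambiguity codes (`B`, `Z`, `J`), stops and
  unknown characters are all fully missing: their tip partial vectors
  are ones, so an all-missing column has likelihood 1 (lnL 0). Gaps are
  not a 21st state, matching common ML engine defaults.
* **Scaling.** Partial likelihood vectors are rescaled per column at
  every internal node with the log scaling factors accumulated, so no
  underflow occurs even for many taxa and low-rate gamma categories.

**Branch-length optimization.** Candidate topologies arrive with
arbitrary (or absent) branch lengths, so lengths are refit per locus and
per topology. The optimizer cycles over edges with bounded derivative-free
scalar searches (Brent, bounds `[1e-8, 10]`). The per-edge objective is
evaluated exactly from "below" (subtree) and "above" (rest-of-tree)
conditional vectors; a depth-first sweep keeps both fresh by refreshing a
subtree's partial vectors as soon as its edges have been updated, making
every accepted move a true gene-lnL improvement. Sweeps stop when a sweep
improves the gene lnL by less than `1e-3` or after 50 sweeps (with a
warning and a convergence flag on the result). Robustness over raw speed
was chosen deliberately: the per-edge profile is unimodal in practice and
the bounded search cannot step outside the feasible region.

**Per-locus model selection.** Branch lengths are optimized once on the
first topology under the first configured model; candidates are then
scored on that fixed tree by `BIC = −2 lnL + k ln(n_sites)` with `k`
counting only the gamma shape (empirical matrices contribute no free
parameters), gamma shapes being refit by a bounded scalar search. Ties go
to the fewer-parameter candidate. The selected model is reused for all
topologies of that locus, keeping the ΔGLS comparison model-matched.
Selecting per locus (rather than on merged partitions) is a deliberate
deviation: ΔGLS is a per-locus quantity, and merged partitioning in
inference engines is a performance device, not part of the statistic.

**Pruned-topology degeneracy.** Each candidate topology is pruned to the
locus' taxon set. When two candidates coincide after pruning (e.g. the
locus samples fewer than the taxa needed to separate the attachments of
the moved clade), the pair is flagged *indistinguishable* and its ΔGLS is
forced to zero downstream. Loci sharing fewer than 4 taxa with a
topology are skipped with a warning.

## ΔGLS: differences, PCA, categorization

With three candidates the ordered-pair differences
`Δ_xy = lnL(T_x) − lnL(T_y)` obey `Δ_12 = Δ_13 − Δ_23` exactly, so the
per-locus triplets live on a plane. PCA of the centered, **unscaled**
triplets (all entries share log-likelihood units, so no standardization)
therefore has rank ≤ 2 and its two explained-variance percentages sum to
100. PC1 is oriented so positive scores go with net support for the
focal topology; PC2's sign is fixed by making its largest loading
positive.

Categorization against the focal topology uses a threshold `τ` (default
2 log-likelihood units):

* **A (uninformative):** all three `|Δ| ≤ τ` ("within ±τ" is inclusive).
* **B (supports focal):** some focal-involving comparison favours the
  focal topology by `> τ` and none disfavours it by `> τ`.
* **C (rejects focal):** the mirror image.
* Loci with evidence in both directions are assigned by the larger
  `|Δ|`, ties going to C, and flagged `conflict`.
* Loci where only the non-focal pair exceeds `τ` stay A with an
  `alternative_discriminating_only` flag — they discriminate between
  the two alternatives but say nothing about the focal resolution.

Category assignment keys on focal-involving comparisons only because the
question the categories answer is support for/against the focal
resolution; the non-focal pair still contributes to the PCA. B/C loci
are additionally flagged by whether their preference holds against both
alternatives or only one (the breakdown used in wheel-chart summaries).

## Treespace, disparity and clade recovery

* **Quartet dissimilarity.** For two gene trees pruned to their shared
  tips, the statistic is the fraction of four-taxon subsets resolved in
  *both* trees that are resolved *differently* (quartets unresolved in
  either tree are excluded from numerator and denominator; an empty
  denominator is defined as 0 and flagged). Resolution is read off the
  four-point condition on unit-branch-length path distances, vectorized
  over all C(s,4) quartets; a brute-force bipartition-based enumerator
  validates it in the test suite. Pairs sharing fewer than 4 taxa are
  undefined and median-imputed (flagged) before ordination.
* **PCoA.** Classical scaling of the dissimilarity matrix (eigenvalues
  of the double-centered `−½D²`). If the most negative eigenvalue
  exceeds `1e-8` in magnitude the Cailliez correction (the smallest
  additive constant making the off-diagonal dissimilarities Euclidean)
  is applied, so all retained axes are real. Axes with eigenvalues
  `> 1e-8` are kept.
* **Disparity.** Mean Euclidean distance of a set of trees to their own
  centroid, computed on **all** retained axes — with all positive axes
  kept, this equals the dispersion in the (corrected) dissimilarity
  space and is invariant to rotation of the ordination.
* **Subsampling nulls.** A subset's disparity is compared with the
  disparities of `n_reps` (default 1000) uniformly drawn subsets of the
  same size; the reported percentile is the proportion of null values ≤
  observed, and a one-tailed "significant reduction in conflict" is a
  percentile ≤ 0.05.
* **Clade recovery.** A named clade is testable on a gene tree when ≥ 2
  members are sampled and at least one non-member is present; it is
  recovered when its sampled members form one side of a bipartition of
  the unrooted tree. Each locus is summarized by the proportion of
  testable clades recovered.

## Gene properties and the usefulness ranking

Fifteen per-locus metrics spanning three groups: *signal* (average
internal-edge bootstrap; Robinson–Foulds similarity to a reference tree,
computed on shared taxa and normalized by the maximum RF for that tip
count), *bias* (saturation = 1 − origin-constrained slope of uncorrected
p-distance on patristic distance; RCFV, the mean per-taxon total absolute
deviation of residue frequencies from the across-taxon mean;
root-to-tip variance under midpoint rooting, with the midpoint located
directly on the longest tip-to-tip path), and *information/rate*
(alignment length, % missing cells, proportions of variable and
parsimony-informative sites, taxon count, total tree length, mean
pairwise patristic distance, treeness = internal/total tree length,
treeness/RCFV, mean per-column Shannon entropy in bits). Midpoint rooting
is used for clocklikeness because pruned gene trees frequently lack
outgroups; p-distances skip pairwise-missing sites.

The usefulness ranking is a PCA of the z-scored (median-imputed) panel.
The usefulness axis is the first of the top two components on which the
signal metrics load with one common sign and the three bias metrics all
load with the opposite sign; it is oriented so signal-rich loci score
high, and ties in the ranking break on locus id. If neither component
matches the pattern the ranking raises an error asking for a manual axis
choice rather than guessing — orchestration layers degrade gracefully by
skipping usefulness-based subsets. The panel is a reconstruction of the
metric families commonly used for usefulness sorting (signal, bias,
information/rate); it is deliberately config-extensible, so reconciling
against any particular published metric list is a data change, not a
code change. Top-fraction subsets take the top `ceil(fraction · n)` loci;
an explicit count is also accepted, since published analyses sometimes
report subset sizes that do not equal an exact fraction of the ranked
list.

## Determinants

* **Vector fitting.** Each property is regressed on the two ΔGLS PC
  score columns; `R²` is the squared multiple correlation and the fitted
  direction (unit vector of the regression coefficients) is the
  direction of maximum correlation in the ordination plane. Significance
  is by permutation of the property across loci (default 10 000
  permutations), `p = (1 + #{R²_perm ≥ R²_obs}) / (1 + n_perm)`; the
  permutation null is computed in vectorized blocks through an
  orthonormal basis of the centered scores. Constant properties return
  `R² = 0, p = 1`; missing values drop the locus pairwise. Because each
  property is tested separately, both raw and Bonferroni-adjusted
  p-values are reported.
* **Classification tree.** Recursive partitioning of the A/B/C factor on
  the numeric property panel. At each node every predictor is tested
  against the factor with a Kruskal–Wallis rank statistic — p-values
  either asymptotic chi-square (default) or by label permutation
  (configurable) — and Bonferroni-corrected across the predictors. The
  node splits only when the minimum adjusted p ≤ α (default 0.05), on
  the winning predictor at the cutpoint maximizing the 2×k chi-square
  association, with minimum node size 20, minimum leaf size 5 and depth
  cap 5. The rank-based statistic with permutation-gated, multiplicity-
  corrected splits reproduces the inferential contract of
  conditional-inference trees while remaining easy to verify; surrogate
  splits and non-numeric predictors are not implemented.

## The synthetic-data generator

`generate_scenario` draws a full study: a random base phylogeny whose
taxa are partitioned into five labelled order-level clades, with three
candidate topologies differing **only** in where the first ("movable")
clade attaches (sister to clade B, sister to clade C, or sister to their
ancestor); pruning the movable clade makes all three identical, which is
what creates per-locus indistinguishability when sampling drops it.

Defaults emulate a deep phylogenomic dataset: 39 taxa; lognormal locus
lengths with mean ≈ 240 columns clipped to [100, 650]; lognormal
per-locus rate multipliers (σ = 0.4 on the log scale, mean 1) scaling
all branch lengths; each taxon dropped independently per locus with
probability 0.2 (≈ the occupancy of filtered supermatrices); clade
subtree branch lengths exponential with mean 0.08 and backbone edges
0.06. Sequences evolve by drawing root states from `π` and propagating
along branches with the model's transition matrices, with per-site
discrete-gamma rate multipliers when the model carries a shape
parameter. Optional compositional bias evolves chosen taxa's terminal
branches under frequency-perturbed models.

Gene-tree error is modelled as a single random NNI applied with
probability `min(1, p_nni · rate_multiplier)` — fast-evolving loci get
noisier gene trees, which couples the panel's signal metrics (bootstrap,
RF similarity) to its bias metrics (saturation, clock violation) the way
real data couple them, and gives the usefulness axis something to find.
Pseudo-bootstrap supports are Beta(4, 1.5) draws stretched to [50, 100]
on unperturbed trees and [20, 90] on perturbed ones. A coalescent mode
is deliberately out of scope: the dissection is agnostic to the source
of discordance, and NNI gives directly controllable error rates.

Every locus' generating topology, tree, rate multiplier and perturbation
status are recorded in a truth table used only by tests and reporting —
no analysis stage reads truth fields.

**What the generator does not emulate:** within-locus gap patterns
(missingness is whole-taxon), site-heterogeneous (CAT-like) profiles,
alignment error, paralogy, and coalescent gene-tree variation. Passing
recovery tests on these scenarios therefore demonstrates the pipeline's
statistical machinery, not robustness to every real-data pathology.

## Problem sizes used in tests and reporting

The reference recovery scenario is 100 loci × 400 columns over 39 taxa
with mixture weights (0.6, 0.2, 0.2), analysed under the generating
model; the recovered focal-supporting fraction is required to fall in
the binomial 95% interval around the truth-table expectation. The
acceptance script runs a 60-locus × 300-column × 24-taxon study with
gene-tree error and compositional bias switched on, sizes chosen so the
full pipeline (including 1000-replicate nulls and 10 000-permutation
scans) completes comfortably on a single CPU. Calibration checks use
200 replicates (null rejection rates, percentile uniformity) and 100
simulations (classification-tree null).

## Known limitations

* Likelihoods assume a single model across sites within a locus (plus
  discrete-gamma rates); no site-heterogeneous mixtures.
* The branch-length optimizer is coordinate-wise; pathological ridges
  between branch lengths could in principle slow convergence (the
  convergence flag records this).
* Quartet dissimilarity is O(s⁴) per tree pair (vectorized); fine for
  tens of taxa, not for hundreds.
* `avg_bootstrap` auto-detects the support scale (≤ 1 treated as
  proportions and rescaled ×100), which misreads trees whose supports
  are genuine percentages all below 1%.
* The classification tree handles numeric predictors only.
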