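# Methods

This note documents the models, numerical choices and known limitations
behind `epibrom`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Trait model and derived traits

A `TraitTable` is a species × trait grid over a 25-trait registry with a
missingness mask (absence, never sentinel values), per-species genus
annotation and a per-cell provenance tag (`measured`, `literature`,
`herbarium`, `derived`, `imputed_phylo`, `imputed_genus`).  Sixteen
registry traits are flagged as clustering members; the two
non-continuous entries are pseudobulb presence (binary) and
photosynthetic pathway (categorical).

Derived traits are filled in a fixed order: leaf index LI = LL/LW; leaf
area LA = LW·LL / 1.5 (cm², from the near-triangular/rectangular
bromeliad leaf outline); tank capacity TC = 0.0041·LA² + 1.929·LA −
22.285 (mL).  The quadratic is negative below ≈ 11.4 cm² and is clamped
to 0 mL — tank volume cannot be negative.  Species known
morphologically not to form tanks carry an explicit `tankless` input
flag and receive TC = 0 directly; tanklessness is never inferred from
the formula.  The pathway call is CAM iff δ13C ≥ −20 ‰ (boundary
inclusive).  Species with data for fewer than five traits are dropped
before analysis.

Input preparation convention (not enforced in code): height, leaf width
and leaf length taken from herbarium descriptions should be the maximum
reported adult values.

## Phylogenetic imputation

The clustering matrix is first coverage-filtered: traits observed for
< 70 % of species are dropped, then species observed for < 70 % of the
remaining traits, repeating to a fixed point (traits always first, so
the result is deterministic).

Missing cells of species present on the phylogeny are filled under a
multivariate Brownian-motion model: stacking the n × p tip matrix
species-major, the joint covariance is C ⊗ R with C the matrix of shared
root-to-ancestor path lengths and R a free p × p trait rate matrix; the
mean is an ancestral trait vector μ replicated over tips.  μ and R are
fitted by maximum likelihood with EM over the missing entries
(conditional means and covariances of the missing block given the
observed block).  Numerical choices:

- columns are standardised internally (the model family is closed under
  per-column affine maps, so imputed values are unchanged while the
  conditioning improves by orders of magnitude when traits span mL to
  thousands of g·m⁻²);
- R is symmetrised each M-step (roundoff asymmetry otherwise compounds
  geometrically across iterations) and regularised by adding
  1e-8·trace/p to the diagonal;
- EM stops when the observed-data log-likelihood improves by < 1e-8 or
  after 500 iterations;
- imputed binary traits are thresholded back to {0, 1} at 0.5.

Imputation runs on raw (untransformed) trait values; the transformation
stack is applied downstream.  Imputed values outside the observed
per-trait range (min/max over non-imputed cells — the only range the
data itself defines) are rejected and revert to missing.  Everything
still missing is filled with the genus mean; cells in genera with no
other value for the trait stay empty.  Species absent from the tree go
directly to the genus-mean stage.  The report's balance invariant —
missing = phylo-imputed + genus-imputed + left-empty, with rejected
cells re-entering the genus pool — is checked programmatically.

## Transformations

Per-trait recipes ending in a min–max rescale to [0, 1] on the analysis
set (bounds are per-run, not stored globals): all clustering traits are
log10-transformed except leaf nitrogen content and δ15N (raw) and the
binary pseudobulb flag (pass-through); TC gets + 0.5 mL before the log
so tankless species remain defined; δ13C is folded to |δ13C| first,
which maps the most negative (C3-like) signatures to the largest
values.  Constant columns rescale to all zeros rather than erroring,
keeping degenerate fixtures usable.  An inverse report (per-trait min,
max, recipe, offset) supports mapping 0–1 coordinates back to raw
units; the |δ13C| fold is not sign-invertible.

Whether the pseudobulb flag entered the published distance computation
unweighted is not stated anywhere; it is included unweighted by default
with a switch to drop it (`include_pb`).

## Ward clustering

The agglomerator minimises Ward's criterion directly: merging clusters
A and B increases the total within-cluster sum of squared Euclidean
distances by ΔSSE = |A||B|/(|A|+|B|)·‖μ_A − μ_B‖², maintained
incrementally from centroids and sizes (equivalent to the
Lance–Williams recurrence with Ward coefficients).  Merge heights
record ΔSSE, so two singletons fuse at half their squared distance —
published implementations differ in the height scale (some report
√(2·ΔSSE)), but all share the same merge order, which is what the
partition depends on.  Ties are broken on the lexicographically
smallest member-index tuples, making the output fully deterministic.
Heights are provably monotone, so cutting to k clusters removes exactly
the last k − 1 merges.  k defaults to 5 and is a user decision (no
automated selection).  A brute-force agglomerator that re-evaluates all
candidate merges from raw points serves as the test oracle; scipy's
`ward` linkage provides an additional merge-order cross-check in tests.

Two-way clustering applies the same agglomerator to the transposed
matrix and reorders rows and columns by both leaf orders for heatmap
display.

## Discriminant validation

Group centroids with pooled within-group covariance (scatter / (n − g)),
shrunk as (1 − λ)·Σ + λ·diag(Σ) with λ = 0.01 by default: with 16
features and group sizes of 5–29 the raw pooled covariance is
near-singular.  A feature with zero within-group variance everywhere
(the binary pseudobulb flag, constant inside every synthetic group) is
*infinitely* discriminative in the Gaussian model; its variance is
floored at λ × the mean of the positive diagonal so distances stay
finite, and distances dominated by such a feature should be read
qualitatively.  Squared Mahalanobis distances between centroids use the
shrunk pooled inverse; classification is nearest-centroid in that
metric.  The Mahalanobis matrix is affine-invariant, symmetric and
zero-diagonal (tested).

## Functional-group rules

Decision order: (1) pseudobulb present → BULB; (2) acicular flag set →
NEB — the flag is an explicit input because species with modest leaf
index (15–19) are still nebulophytes by morphology, so LI alone cannot
decide; only when the flag is absent does a fallback fire (LI ≥ 40,
between the reported group means of 15 and 83, with TC < 2 mL);
(3) CAM: TC ∈ [2, 61] mL → SHALLOW_T, TC > 61 → CAM_T (the shallow
window is stated inconsistently as 2–60 and 2–61 mL in different places
of the source material; the engine uses the inclusive [2, 61] from the
explicit threshold statement); a tankless, non-acicular,
non-pseudobulb CAM plant matches no published rule and returns
UNCLASSIFIABLE with NEB/BULB as advisory candidates; (4) C3: TC > 5 mL
→ C3_T, TC ≤ 5 mL → SHALLOW_T (following the documented precedent of
C3 species with ~2 mL tanks grouping with the shallow tanks; species
with TC in (2, 5] may be edge cases of this choice).  Unresolvable
pathway or tank capacity always yields UNCLASSIFIABLE with a reason.

Cluster reconciliation applies two overrides, each logged: CAM species
landing in the C3-tank cluster move to CAM_T (pathway mismatch), and
acicular species landing in the shallow-tank cluster move to NEB.  The
operation is idempotent.

## Group statistics

Spearman correlations use pairwise-complete observations, midranks for
ties and the t-approximation for two-sided p-values; cells with fewer
than three complete pairs are undefined.  No multiple-testing
correction is applied by default, matching the reporting style the
pipeline emulates; a Holm option exists behind a flag.  The "strong
correlation" report filter is p < 0.05 and ρ² > 0.60.

Kruskal–Wallis uses the tie-corrected H with a χ² p-value on g − 1 df.
Pairwise Wilcoxon rank-sum post-hocs use exact enumeration for tie-free
samples with n ≤ 10 per group and the tie/continuity-corrected normal
approximation otherwise.  ANOVA/Tukey follow the classical one-way
F and studentized-range procedures (scipy).  Compact letter displays
are built by a greedy insert-absorb algorithm and every emitted display
is checked against its pairwise p matrix (groups share a letter iff
their pairwise p ≥ α).  An omnibus report whose H exceeds the χ²
critical value while p ≥ α is internally inconsistent; the comparison
object flags such reports in its notes rather than emitting them
silently.

Environmental comparisons use raw occurrence records as the comparison
unit by default (a per-species-mean mode exists and is flagged
non-default).  Ecological-zone summaries count species presence, never
abundance: a species contributes at most 1 per zone regardless of
record count.

## Synthetic data

The generator emulates the structure of the compiled trait database:
76 species split 29/22/12/8/5 across C3 tanks, CAM tanks, shallow
tanks, nebulophytes and pseudobulbs (the published 38/29/16/11/5
percentages at the cluster-analysis sample size), 16 clustering traits,
7.2 % missing cells, a pure-birth phylogeny, and 20 occurrence records
per species.

Trait values are drawn from per-group archetypes calibrated to the
published medians/ranges and directional contrasts (nebulophytes: LI ≈
85, tiny leaves, TC = 0; pseudobulbs: thick succulent leaves, TC = 0;
shallow tanks: TC ≈ 20 mL within [2, 61]; CAM tanks: large, TC ≈ 650
mL; C3 tanks: δ13C ≈ −28.5 ‰, highest SLA).  Positive size-like traits
are log-normal (SDs on the log10 scale, ≈ 0.2 dex); signed signatures
(δ13C, δ15N) and contents are Gaussian.  A Brownian-motion deviation
simulated along the tree (rate 0.003 per unit depth, common correlation
0.3 across traits) adds phylogenetic signal; at the default tree depth
this yields correlated per-species deviations of ≈ 0.1 dex, well inside
the ≈ 0.5 dex group contrasts, so the archetypes remain separable — a
deliberate property of the generated study conditions, since the
configuration validator requires group means to respect the rule
thresholds they are meant to trigger.

The Yule simulator starts from two lineages, holds Exp(kλ) while k
lineages exist and splits a uniform lineage until n tips, plus a final
Exp(nλ) hold, so the expected root-to-tip depth is Σ_{k=2..n} 1/(kλ)
(tested against 200 replicates).  Masking is
missing-completely-at-random, never dropping a species below five
observed traits, with the achieved count within one cell of the
target.  Climate niches are Gaussian per group (nebulophytes driest and
most evaporative, C3 tanks wettest, coolest and highest) and
ecological zones are categorical draws per group.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: opportunistic (non-random) missingness
concentrated in hard-to-measure physiological traits; taxonomic
autocorrelation between genera and functional groups (synthetic genera
cycle across groups); intra-specific trait variation (one vector per
species); measurement error structure from herbarium shrinkage; and
spatial sampling bias in occurrence records.

## Imputation benchmarks

Two scenarios compare Brownian-motion imputation against genus means on
identical masked cells.  *Strong signal*: traits evolve under
correlated BM on a Yule tree and genera are clades of that tree, so
both imputers are informed but the BM imputer exploits the full tree
and trait covariance.  *Star tree*: independent traits on a star
phylogeny — no signal.  In the star scenario the genus mean of a small
genus is a strictly noisier estimator of the common mean than the GLS
mean even though neither carries signal (MSE ratio ≈ (1 + 1/n)/(1 +
1/n_genus)); the scenario therefore uses two large genera so that
estimator-efficiency effects do not masquerade as phylogenetic signal.
Rate-matrix recovery is reported as the relative Frobenius error of the
replicate-averaged fitted R: per-replicate sampling error at 50 tips is
irreducible (≈ 25 % for p = 3), while the average converges.

## Problem sizes

Default analysis sizes are those of the emulated study: 76 species × 16
traits, trees of 50–76 tips, 10,000 replicates for the Kruskal–Wallis
null calibration, 200 random instances for the Ward oracle comparison,
8 replicates for the imputation benchmarks and 20 for rate-matrix
recovery.  The full EM at 76 species × 16 traits takes seconds to about
a minute depending on convergence.

## Known limitations

- The EM imputer assumes one multivariate BM regime over the whole tree
  (no Ornstein–Uhlenbeck, no rate shifts) and a complete tree topology
  with branch lengths; it does not propagate imputation uncertainty.
- The rule engine's CAM/tankless/non-acicular gap and the C3 (2, 5] mL
  window are acknowledged blind spots of the published rules, surfaced
  as UNCLASSIFIABLE outcomes and a documented design choice
  respectively.
- Mahalanobis distances involving groups separated by a zero-variance
  feature depend on the variance floor and are qualitative.
- The trait registry's record counts come from two printed summaries
  whose totals disagree by 100 (16,574 vs 16,674); both sums are
  exposed and no reconciliation is attempted.
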