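# Methods

This note documents the models, defaults and numerical choices behind
`midgutmet`, and what the synthetic benchmark does and does not demonstrate.

## Synthetic midgut atlas

`simulate_midgut` draws a gene × cell integer matrix emulating the structure
of the adult fly midgut epithelium.  Eight fine cell types are generated —
quiescent ISC (qISC), proliferating ISC (pISC), enteroblasts (EB), a
differentiating-enterocyte intermediate (dEC), three regionalized enterocyte
fates (aEC, mEC, pEC) and enteroendocrine cells (EE) — with default
proportions 0.08/0.09/0.08/0.15/0.15/0.15/0.15/0.15 over 1500 cells and 200
genes.  The three progenitor types share the cluster label `ISC_EB`, which is
what the trajectory analysis consumes; the fine types are returned as ground
truth.

**Expression programs.**  Each type's program is a vector of relative
expected counts assembled from gene modules: a progenitor module (high in
qISC/pISC/EB, low in enterocytes), a shared enterocyte module (high in all
EC fates, intermediate in dEC), one module per regional EC fate (high only in
its own fate; dEC expresses none of them, since expressing all three at
intermediate level would geometrically push dEC *away* from every fate), an
EE module, and lognormal background genes shared by all types (drawn once
from a fixed internal seed, so programs are identical across simulation
seeds).  Marker genes follow the study's gates: esg active in qISC/pISC/EB,
Dl in pISC, klu in EB, pros in EE.  "Active" means a high-mean program
(relative mean 20); "off" means a near-zero mean (2 × 10⁻⁵) that essentially
never yields a count at the default depth yet keeps positivity thresholds
meaningful.  Eight fatty-acid-metabolism genes (CG3902, CG4860, CG5599,
CG9547, CG31075, Mtpalpha, whd, yip2) carry a multiplicative pseudotime
gradient exp(direction · effect · t) with default direction −1 and effect
1.5, i.e. a ~4.5-fold decline from stem cells to terminal fates.

**Counts and dropout.**  Per-cell library sizes are uniform on
[2000, 4000] expected counts; the per-cell size factor is the library size
over its geometric mean.  Counts are gamma-Poisson (negative binomial,
dispersion 0.3, variance μ + 0.3 μ²), chosen over Poisson so the
normalization estimators face realistic overdispersion.  Dropout is
Bernoulli zeroing with logistic probability 1/(1 + exp(slope · (log μ −
midpoint))), defaults midpoint 0 and slope 1 (≈16% of non-zero entries
dropped at default depth).  Dropout uses an RNG stream separate from the
count draws, so raising the midpoint with the same seed only ever adds
zeroed entries (a monotonicity the tests rely on).  Pseudotime intervals are
depth-indexed slices of [0, 1]: a type at tree depth d occupies
[d, d + 1]/(d_max + 1), with cells uniform inside their slice.

**What the generator does not model:** ambient RNA, doublets, batch effects,
UMI structure, EE subtype heterogeneity, or any region-specific library
depth.  Passing tests therefore show the algorithms behave correctly under
clean cluster-plus-gradient structure with overdispersion and dropout — not
that they are robust to every artefact of real droplet data.

## Preprocessing

TPM uses the longest annotated transcript per gene; genes without annotation
are dropped with a warning (a `median` policy is available — silent guessing
corrupts TPM).  All-zero cells stay all-zero and are flagged, never NaN.
The log transform is log2(x + 1); the pseudocount is exposed.  Order of
operations follows the study: size factors → TPM → log2 → imputation.

**Imputation** is a desk-scale re-specification of the scImpute idea, not a
wrapper: cells are k-means clustered (default k = 8, matching the number of
generated programs; k = 5 was observed to merge dEC with a regional fate and
let imputation bleed expression across clusters) on the top 10 principal
components of the log matrix.  Only genes with dropout rate strictly above
0.5 are eligible, to prevent over-imputation of well-measured genes.  Within
each cluster a two-component spherical Gaussian mixture on the gene's log
values separates a near-zero dropout component from an expressed component;
zero entries whose posterior dropout probability exceeds 0.5 are replaced by
a similarity-weighted (Gaussian kernel in PC space, bandwidth the median
squared neighbour distance) average over same-cluster cells reliably
expressing the gene.  Non-zero entries are never modified.

One guard is deliberate and load-bearing: a zero entry is only imputed when
the *expressed* component holds the majority of the cluster (mixture weight
> 0.5).  The progenitor subtypes differ by only three marker genes and no
clustering separates them; without the guard, Dl and klu zeros inside the
mixed ISC/EB cluster would be "recovered" from the minority of expressing
cells, turning most progenitors into double positives and destroying the
marker gates.  The corollary is that a gene silenced in the majority of a
cluster is read as biologically off there — imputation recall is traded for
gate specificity.  Fidelity to the published scImpute tool is explicitly not
claimed.

## Normalization

All four estimators use reference genes with dropout rate < 0.75 and rescale
factors to geometric mean 1.

- **Upper-quartile:** the 75th percentile of the cell's non-zero reference
  counts.
- **TMM:** reference cell = the one whose upper-quartile fraction is closest
  to the mean; M and A values over genes non-zero in both cells; double
  trimming (30% of each M tail, 5% of each A tail — the published defaults,
  exposed in the API); delta-method precision weights
  1/((N−y)/(Ny) + (N_r−y_r)/(N_r y_r)); the factor is the cell's reference
  library size × 2^(weighted mean M), making the factor scale-equivariant.
- **RLE:** median over reference genes of count / per-gene geometric mean;
  when no gene is non-zero in every cell it falls back to positive-only
  geometric means with a warning.
- **Deconvolution:** within each group (cell-type label), cells are ordered
  on a ring by library size (ties broken by cell id); pools of ring-
  consecutive cells (sizes 21…101, clipped to the group) each contribute one
  equation — the sum of member factors equals the median ratio of the pooled
  profile to the group average profile.  The stacked system is solved by
  least squares with low-weight (0.1) per-cell ratio anchors for
  conditioning; non-positive solutions are clamped to the smallest positive
  one; group blocks are placed on a common scale by the median ratio of
  group-average to global-average profiles.

The bake-off (`evaluate_normalizations`) computes, per method, relative
log2-TPM expression (cell value minus the gene's grand mean), pools it per
cell type and scores the mean two-sample Kolmogorov–Smirnov statistic over
all type pairs — a nonparametric, distribution-level divergence.  The
minimizing method wins; ties break by the fixed order UQ, TMM, RLE,
deconvolution, and a failing method is recorded, not skipped.  On synthetic
data with strong planted factors the pooled method wins this comparison
against upper-quartile in essentially every seed, which is the behaviour the
method-selection step is designed to reward.

## Pathway activity

Relative expression is computed on **linear** TPM (ratio of means, matching
the score's definition; scoring log values is available by transforming the
input).  The pathway score is the unweighted mean of r(g, t) over the set's
genes present in the matrix; pathway-multiplicity weighting and outlier
trimming are not applied by default.  The permutation test shuffles the
type-label vector B times (default 5000) and recomputes all scores; the
p-value is two-sided in the distance from the neutral value 1 with the +1
correction, so p ≥ 1/(B + 1) and never 0.  A fixed seed gives bitwise
reproducible p-values.  Calibration was checked on null data (one shared
program, labels exchangeable): across 200 random pathways × 4 types at
B = 500, the p-value ECDF sits within KS distance ≈ 0.02–0.04 of uniform.

## Gating

Positivity is log2 expression > 0 on imputed values by default — any nonzero
normalized signal counts, since "off" markers essentially never fire in the
generator and imputation has already filled likely technical zeros of
genuinely expressing cells.  The threshold is configurable per marker; rules
are evaluated in order (pros⁺ exclusion first, then esg gating, then the
Dl/klu combinations) and every cell receives exactly one class.

## Trajectory

Lineage inference is a re-implementation of the centroid-MST-plus-
principal-curve construction, not a wrapper: PCA (d = 10 by default;
deterministic sign convention with the largest-magnitude loading positive),
cluster centroids, Kruskal MST with lexicographic tie-breaks, root→leaf
paths as lineages.  Pseudotime is the arc-length projection onto the
piecewise-linear centroid curve; an optional project-average refinement
(≤10 iterations, relative tolerance 1e-4) nudges interior vertices toward
the local cell mass.  Simultaneous principal-curve shrinkage is out of
scope.  The t-SNE embedding is seeded and used for visualization only.

Gene trends are lowess fits (span 0.5) evaluated on a 100-point grid.  The
fit runs against the pseudotime **rank** rather than raw t: cells clump at
cluster centroids leaving long empty gaps, where a fixed-width smoother is
dominated by a handful of stray cells.  The direction label compares the
fitted end against the start with δ = 0.25 log2 units and tolerates
counter-movement up to max(δ, 30% of the net change) — boundary wiggles of a
smoother should not flip a monotone call; a curve that rises and falls by
comparable amounts is labelled non-monotone, and one whose whole range is
within δ is flat.

## miRNA consensus and enrichment

The consensus rule keeps genes present in ≥ k of N prediction lists
(defaults k = 3, as in the study's 3-of-4 rule, which yields the packaged
eight-gene FAO target table).  Enrichment replaces the discontinued online
GO service with a local upper-tail hypergeometric test against user-supplied
GMT categories intersected with the universe; significance is called on raw
p < α = 0.05 (the study's stated criterion) with Benjamini–Hochberg adjusted
values reported alongside.  The default universe is the supplied universe
file, or the union of the lists when none is given.

## CRISPR design

`find_targets` scans both strands for 20-mers followed by NGG (the standard
SpCas9 PAM adjacent 3′ of the protospacer).  `count_offtargets` is an
exhaustive Hamming scan (both strands, NGG+NAG PAMs, ≤3 mismatches by
default) minus the single best on-target site — a local stand-in for
genome-scale web tools, suitable for the ≤10 kb synthetic loci used here.
Primer construction is fully determined by constants verified against the
published six-guide array: forward = flanking-site prefix + TGCA + guide +
scaffold anchor; universal reverses carry two internal sites of the opposite
enzyme; the final reverse carries the last guide verbatim (not reverse-
complemented — this reproduces the published strings; whether the printed
guides are top- or template-strand is a biological question the code does
not resolve).  The simulated assembly concatenates guide + scaffold + tRNA
cassettes, where the tRNA's 3′ end supplies the TGCA overhang for the next
guide, and asserts no BbsI/SapI recognition site survives (scarless).  An
even number of guides is required: n guides give n − 1 fragments with
alternating enzymes, and the final reverse primer is BbsI-flanked, which
only matches an odd final fragment index.

## Problem sizes and determinism

Default test and benchmark sizes are 1500 cells × 200 genes for the full
pipeline, 200–400 cells for estimator benchmarks, B = 500 permutations for
calibration and power runs (B = 5000 remains the analysis default), and
5–10 kb synthetic genomes for off-target oracles — sizes at which every
check runs in seconds to a couple of minutes on one CPU while leaving the
statistical conclusions stable across seeds.  All randomness flows through
explicit integer seeds; equal (config, seed) reproduces every matrix,
p-value and pseudotime bitwise.

## Known limitations

- The imputer's majority-expressed guard deliberately refuses genes silenced
  in most of a cluster; true dropout above 50% within a cluster is not
  recovered.
- Deconvolution factors are only approximately scale-equivariant (the pooled
  equations are nonlinear in a single cell's counts); planted-factor
  recovery, not exact equivariance, is the tested contract.
- Pseudotime is a polyline projection; cells beyond the root or terminal
  centroid clamp to the path ends, compressing the extremes of each lineage.
- The off-target count ignores bulges, chromatin and scoring models; it is a
  mismatch census, not an activity prediction.
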