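# Methods

This note documents the model behind `divikit`, the defaults and numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## The divisive model

The data model is a dense nonnegative matrix of abundances, rows =
observations (e.g. one spectrum per imaging pixel), columns = features
(e.g. peak intensities). The method assumes nothing about spatial layout;
coordinates are carried only for visualisation.

Segmentation is a recursion over regions. Each region independently:

1. re-derives its informative feature subset (variance-based mixture
   filtering over the globally surviving pool),
2. tests itself for homogeneity (two-trial GAP on subsamples),
3. if heterogeneous, chooses a number of clusters by a subsampled
   approximate Dunn index and splits with deterministically seeded K-means,
4. recurses into the children.

The central assumption is that the molecular identity of a subregion is a
*relative pattern* over a modest subset of features, and that this subset
differs between levels of the hierarchy: features that are flat across a
parent region may be the discriminating ones inside it. This is why the
variance filter is recomputed per node over the globally surviving feature
pool rather than nested inside the parent's mask — nesting would forbid a
feature dropped at one level from ever re-emerging deeper down, defeating
the purpose of local adaptation.

## Feature filtering

Per node, per feature, the statistic is the log₁₀ of the abundance variance
across the node (log₁₀ mean abundance for the one-shot global noise filter).
Base 10 is conventional for abundance data; any base gives identical masks
because thresholds and statistics transform together. Features with a zero
statistic (all-zero or constant columns) receive a `-inf` sentinel, are
excluded from mixture fitting, and are always dropped: a log of zero is
undefined and a zero-variance feature cannot discriminate anything.

The statistic vector is decomposed into a 1-D Gaussian mixture fitted by EM
(k-means++ initialisation, 10 restarts, tolerance 1e-6 on the
log-likelihood, at most 1000 iterations, variance floor 1e-6 · var(x));
K = 1..10 components are fitted and the BIC minimiser is kept, ties to the
smaller K. Components attracting < 1 % of the features under
maximum-posterior assignment are discarded as numerical artefacts and the
weights renormalised. Fewer than 10 finite statistics, or a constant
statistic vector, degrade gracefully to a keep-everything-finite mask: with
so few points a mixture decomposition is meaningless.

Thresholds are the equal-density points of adjacent weighted components,
found by Brent's method bracketed by the two means; when the weighted
densities do not change sign between the means (strongly overlapping or
dominated components) the midpoint of the means is used and the event
logged. The variance filter walks thresholds from the topmost down until at
least `ceil(min_feature_fraction · n_pool)` features survive, falling back
to a straight top-variance cut at that count when no threshold satisfies
the bound; a single-component model keeps every finite feature. The
abundance filter keeps everything at or above the *first* crossing.

## Stop rule

Homogeneity is a two-trial GAP comparison. For a subsample `S` of the node
(|S| = `subsample_size`, without replacement; the full node when smaller):

    W(k)   = Σ_clusters Σ_members d(member, centroid)
    gap(k) = mean_b log W*_b(k) − log W(k),   b = 1..gap_n_reference

with the reference sets drawn uniformly within the per-feature [min, max]
bounds of `S` and clustered by the identical deterministic pipeline. The
subsample votes homogeneous iff `gap(1) ≥ gap(2)`; the node stops when a
strict majority of `n_subsamples` votes agrees (a tie keeps splitting — the
cost of one extra split is lower than that of a prematurely frozen region,
and deeper nodes get re-tested anyway).

The two-trial statistic is always computed in **Euclidean** geometry, even
when the clustering metric is correlation. This is a deliberate design
choice, made after measuring the alternative: under correlation distance,
row-normalised heavy-tailed (log-normal-like) data is systematically easier
to split into two than the uniform bounding-box reference, so
`gap(2) − gap(1)` sits at a positive offset (≈ +0.02..+0.17, far beyond the
reference standard error) on *completely structureless* regions and the
recursion never stops. In Euclidean geometry — the geometry the GAP
statistic is defined in — structureless log-normal regions vote homogeneous
(margins ≈ +0.01..+0.03) while planted structure votes split with margins an
order of magnitude larger (≈ −0.16..−0.23). The clustering itself, and the
Dunn-based model selection, still use the configured metric throughout.

No one-standard-error correction is applied: the decision aggregates over
subsamples instead, which plays the same variance-controlling role.

## Cluster-number selection

For each candidate k the full node is clustered once (deterministic
seeding, see below), and the quality of the *fitted* partition is scored as
the mean over `n_subsamples` subsampled evaluations of the approximate Dunn
index

    Dunn = min_{i<j} d(c_i, c_j)  /  max_i ( 2 · mean_{x ∈ C_i} d(x, c_i) )

(centroid separation over twice the mean member-to-centroid spread; +inf
when all clusters are singleton-tight). This O(nk) surrogate replaces the
O(n²) pointwise Dunn index — the exact index is additionally so brittle
that a single mislabeled point collapses its numerator, which makes the
centroid form not just cheaper but better behaved; the test suite asserts
their directional agreement as blob separation varies. The best k maximises
the mean subsampled Dunn, ties to the smallest k. Candidates that produce
an unrepairable empty cluster, or exceed the number of KD-tree boxes, are
skipped; if none survives the node becomes a leaf (`no_valid_split`).

## Deterministic seeding

Random K-means initialisation would make tissue segmentations
irreproducible run-to-run. Instead the node is compressed by a KD-tree
(split the widest-range dimension at the median — stable-argsort halves, so
ties are deterministic — until leaves hold ≤ `ceil(leaf_fraction · n)`
observations); each leaf becomes a box with its centroid and weight.

* Seed 1: the box centroid at `seed_percentile` of the weighted empirical
  CDF of the metric distance from the global centroid (nearest-rank rule;
  distance ties resolved to the lower box index). A high percentile picks a
  moderately outlying box — a region boundary rather than the bulk mean.
* Seed 2: the same construction with distances measured from seed 1,
  excluding its box.
* Seed j ≥ 3: the percentile of the **Euclidean orthogonal distance to the
  affine hull** of the seeds chosen so far (a line/hyperplane has no
  meaning under correlation distance; the geometric construction is
  Euclidean in the filtered space). If every candidate is numerically on
  the hull (< 1e-12), the fallback CDF is the metric distance to the
  nearest existing seed.

K-means then runs standard Lloyd iterations under the configured metric
with arithmetic-mean centroid updates, stopping when labels are unchanged
or after 300 iterations. An emptied cluster is re-seeded at the observation
farthest from its current centroid, at most k repairs per iteration.
Correlation distance is `1 − Pearson r`; a constant observation, for which
r is undefined, is defined to be at distance 2 (maximal) from everything.

## Configuration

| parameter | default (`oscc`) | `kidney3d` | meaning |
|---|---|---|---|
| `distance` | correlation | correlation | metric for clustering and Dunn |
| `max_k_per_level` | 10 | 10 | k sweep upper bound per node |
| `min_cluster_size` | 200 | 200 | nodes smaller than this never split |
| `min_feature_fraction` | 0.01 | 0.005 | floor on the locally kept features |
| `kdtree_leaf_fraction` | 0.01 | 0.001 | KD-tree leaf capacity ÷ n |
| `seed_percentile` | 99 | 95 | seeding percentile of the distance CDF |
| `n_subsamples` | 10 | 10 | subsamples for GAP votes and Dunn means |
| `subsample_size` | 1000 | 5000 | observations per subsample |
| `gap_n_reference` | 10 | 10 | reference draws per GAP evaluation |
| `max_leaf_size_stop` | — | 50 000 | stop splitting regions at/below this size |
| `max_depth` | 20 | 20 | recursion guard |

The two presets carry the published parameterisations of the 2-D
oral-cancer and 3-D mouse-kidney analyses. `max_leaf_size_stop` implements
the large-volume variant of the stop semantics ("regions this small are not
worth subdividing at atlas scale") as a separate field rather than
overloading `min_cluster_size`, whose meaning ("never split below this") it
complements. `max_depth` = 20 has no biological meaning; it bounds
pathological recursion on adversarial input. Seeding percentile and leaf
fraction are run-level constants, not adapted per depth.

## Synthetic data

The generator emulates three properties of peak-picked MSI matrices:
log-normal-like positive abundances (`10^(base + shifts + N(0, log_sd))`),
a planted hierarchy in which each split is driven by its own disjoint
feature subset, and a majority of noise features sharing one global mean.
Defaults: `base_log_mean` 2.0 (peak intensities of order 100),
`log_sd` 0.25 (roughly ×1.8 per standard deviation, a realistic
multiplicative spread for peak intensities).

Each split distributes its informative features into one exclusive block
per child; a child's observations are shifted `+effect` on its block only.
Two properties of this design matter:

* siblings differ by an *up-regulation pattern*, which both Euclidean and
  correlation geometry can see (a uniform elevation across all retained
  features would be invisible to correlation distance, and down-shifts are
  nearly invisible on the raw intensity scale, where `10^(2−1)` sits close
  to baseline while `10^(2+1)` dominates);
* with equal-size top-level blobs, a sub-split's features are elevated in
  half as many observations as a top-split's, hence carry about half the
  global variance and land in a lower mixture component of the root's
  variance decomposition. The root filter therefore masks them until the
  recursion isolates their branch — the nested-signature regime the local
  filtering exists for. Unequal top sizes break this (the smallest blob's
  markers fall into the same tier as sub-split markers and get filtered
  away at the root, verified empirically), which is why the standard
  benchmark uses equal thirds.

What passing the synthetic benchmarks shows: the recursion recovers planted
nested structure level-by-level at realistic size (5000 × 500, 5 %
informative features per split, 1 log-unit effects), stops on structureless
regions, and scales to 10⁵ observations touching only subsampled quantities
for quality estimation. What it does not show: robustness to correlated
noise, batch effects, spatial autocorrelation, isotope envelopes, or
intensity-dependent noise — none of which the generator emulates — nor
anything about preprocessing (peak picking, baseline removal), which is out
of scope entirely.

## Evaluation machinery

Cluster labels are matched to annotated regions (ROIs) in two stages.
First, per ROI in priority order (medically most relevant first), clusters
are sorted by the fraction of their area inside the ROI and accumulated
greedily, keeping a cluster iff it strictly increases the Dice coefficient
of the union — the strict-increase rule makes the selection unique and, on
every random instance with ≤ 12 clusters the suite enumerates, reproduces
the exhaustive-subset optimum. Second, clusters claimed by several ROIs are
resolved by enumerating assignment scenarios (full Cartesian product,
capped at 10⁵ with a greedy priority-order fallback beyond) and keeping the
scenario whose induced labelling maximises the adjusted Rand index against
the ROI labelling. Unclaimed clusters become "other".

Quality indices: adjusted Rand (global composition), multi-cluster Dice of
the primary ROI (target-region coverage), and an externally supplied
spatial-structure score rescaled to [0, 1] (the package consumes the
number; computing it is out of scope, and degenerate single-cluster
segmentations conventionally receive 1.0). The overall-quality distances
combine a triplet as `d(0,0,0) = ‖v‖₂` and `d(1,1,1) = ‖1 − v‖₂` after
clipping to [0, 1]. Rank aggregation uses average ranks for ties (so tied
configurations share fractional ranks) and sums ranks per method; lower is
better.

## Numerical and degenerate-input conventions

* `log W` in the GAP statistic uses `log(W + 1e-12)` so perfectly tight
  clusters do not produce −inf.
* All subsampling is without replacement with sub-seeds drawn from one
  `numpy` generator owned by the run (`rng_seed`), consumed in
  deterministic depth-first order — identical config + seed ⇒
  byte-identical tree JSON.
* Tree JSON stores observation membership only at the leaves; internal
  memberships are the sorted unions of their children, which reconstructs
  the original indices exactly.
* The empty mask, empty selection and single-component cases all degrade to
  permissive behaviour (keep all features / no threshold) rather than
  erroring: a filter should never abort a segmentation.

## Known limitations

* The Euclidean-GAP stop rule is a calibrated design choice, not a theorem;
  metrics whose cluster structure is invisible in Euclidean geometry (pure
  pattern contrasts of equal magnitude) could stop too early.
* The approximate Dunn index scores convex, centroid-shaped clusters;
  elongated or nested manifolds will not be ranked meaningfully.
* The mixture filter assumes the variance histogram is a mixture of a few
  roughly Gaussian components on the log scale; strongly skewed unimodal
  histograms can be over-decomposed by BIC, shrinking the kept set toward
  the upper tail (the `min_feature_fraction` floor bounds the damage).
* Scenario enumeration in label normalisation is exponential in the number
  of multiply-claimed clusters; the 10⁵ cap with greedy fallback keeps it
  bounded at the cost of optimality in extreme cases.
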