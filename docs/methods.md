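# Methods

## Problem and approach

Choosing the number of clusters K for a samples-by-variables matrix
(typically log2 gene expression, variables = genes) is notoriously
sensitive to three arbitrary choices: the clustering algorithm, the
internal validity index used to score candidate partitions, and the
variable subset the data were reduced to.  This package maps all three
at once.  The matrix is reduced to nested subsets of the top-variance
variables (sizes n₁ < n₂ < … , each a prefix of the next under one
global variance ranking); every subset is clustered by every algorithm
in the roster for every K in a range (default 2..10); every resulting
partition is scored by every validity index.  After locally pruning
untrustworthy algorithms and indices, the surviving scores are
standardized, orientation-corrected and averaged into a single K × n
matrix of "Z-measures" whose topography the user reads as a stability
map: ridges that persist across subsets indicate a robust K.

## Algorithm roster

Eight hard-partition algorithms that accept a user-specified K:

| name | method | notes |
|---|---|---|
| hierarchical | Ward agglomeration on Euclidean distances | Ward.D2 update convention |
| agnes | agglomerative nesting | Ward update applied to squared distances (Ward.D convention); can merge in a different order than `hierarchical` |
| diana | divisive analysis | splits the largest-diameter cluster via the splinter procedure (seed = member with max average dissimilarity; members move while the gain is positive) |
| kmeans | Lloyd iterations, squared Euclidean | 10 restarts, best inertia kept |
| pam | partitioning around medoids | greedy BUILD, then best-improvement SWAP passes |
| clara | PAM on sub-samples | 5 replicates of size min(N, 40 + 2K); all samples assigned to the nearest medoid; lowest total dissimilarity kept |
| som | self-organizing map, 1 × K linear grid | batch training, 100 epochs, Gaussian neighbourhood decaying linearly over the first half of training (classic two-phase schedule); units initialised as contiguous group means along the first principal direction, so the fit is deterministic |
| sota | self-organizing tree | binary tree growing by cell division of the leaf with the highest mean member-to-centroid distance, refined by a two-centroid relocation restricted to the leaf; grown until exactly K leaves |

Fuzzy and model-based algorithms are excluded by design: they need not
return the requested K.  No input scaling is applied — only validity
*outputs* are standardized, never the data.  Tree-structured algorithms
(hierarchical, agnes, diana, sota) are fitted once per subset and read
off at every K.  All stochastic algorithms take an explicit seed;
identical seeds give identical labels.

Restart counts, SOM epochs and CLARA replicate counts are exposed
configuration with the defaults above; they follow the conventions of
the classic implementations of each algorithm.

## Validity indices

Seventeen pairwise-distance indices (the `cluster.stats` roster:
average between/within-cluster distance, silhouette width,
Calinski–Harabasz, connectivity with L = 10 neighbours, Dunn and Dunn
2, entropy of cluster sizes, Goodman–Kruskal G2 on distance
concordance with ties counting toward neither direction, G3,
max diameter, min separation, Pearson's Γ, separation index with the
smallest 10% of cross-cluster gaps, widest within-cluster gap as the
largest MST edge, within-cluster sum of squares, and the
within:between ratio) are computed from one distance matrix per
subset.  `avg_within` is the plain mean over within-cluster pairs
(pair mean, not a cluster-size-weighted mean of cluster means).  The
within/between/total sums of squares are obtained through the distance
identity Σ_c Σ_{i,j∈c} d²ᵢⱼ/(2n_c); the test suite cross-checks them
against direct centroid computations.  Indices undefined for a
degenerate labelling are reported absent (NaN), never coerced to zero.

The gap statistic is Tibshirani's uniform-over-feature-ranges
formulation: Gap(k) = (1/B) Σ_b log W*_kb − log W_k with
W_k = Σ_c D_c/(2n_c), B = 50 by default (20 in the benchmark), plus the
usual standard error sd(log W*)·√(1+1/B).  Reference draws are shared
across algorithms and across K within a subset — each draw is clustered
once per algorithm over the whole K range — and reference clusterings
use reduced stochastic effort (k-means with a single restart, CLARA
with 2 replicates, SOM with 10 epochs).  The Monte-Carlo error of the
B-draw average dominates the restart-to-restart variance of any single
reference clustering, so this changes the gap values only within their
own standard error while making the full grid affordable.

Each index carries an orientation used when averaging into the map
(higher-better: avg_between, silhouette, CH, Dunn, Dunn2, G2, gap,
min separation, Pearson Γ, separation index; lower-better: the rest).

## Local roster optimization

*Algorithms.* For each algorithm, the fraction of its grid runs
producing any cluster with fewer than `min_size` = 3 members is
computed; algorithms strictly above the mean fraction are dropped.
Tiny clusters desynchronise the K at which the major splits of the
data appear across algorithms, which smears the map.

*Metrics.* For each index, the fraction of its K-sequences (one per
algorithm × subset) that are non-strictly monotone is computed;
indices strictly above the median fraction are dropped.  Monotone
indices carry a systematic preference for low or high K and no peak
information; constant sequences count as monotone for the same reason.
Both rules use strict inequality, so ties at the threshold are
retained and an all-clean roster loses nothing.

*Final metric set.* Surviving indices are hierarchically clustered
(average linkage on 1 − |r|, Pearson r over all grid cells,
pairwise-complete) into `n_groups` groups (5 in the simulated
benchmark, 4 by default for expression data), and the one-per-group
selection minimising the mean absolute pairwise correlation of the
chosen set is taken — exhaustively when the number of combinations is
at most 10⁵, greedily group-by-group beyond that.  The published
description ("the set with the lowest mean correlation within each
cluster") is ambiguous between this set-level rule and picking each
group's least-correlated member; the set-level rule is implemented
because it directly optimises the property the final set is used for
(low redundancy when averaged).

## The Z-measure map and its optima

For each final metric and retained algorithm, the K × n matrix of raw
values is oriented (lower-better negated) and z-scored jointly over
all its cells (mean 0, sd 1, ddof = 1); z-scoring per column would
erase the cross-subset shape the map is meant to display.  Slabs are
averaged over algorithms, then over metrics, unweighted.  A metric
with zero variance over the grid is dropped from the average with a
warning.

Per subset column, interior local maxima are points at least as high
as both neighbours and strictly higher than one; a flat plateau of
equal maxima counts once, at its smallest K.  The red point is the
maximum with the most negative second difference v_{K+1} − 2v_K +
v_{K−1} (the steepest peak); with no interior maximum it reverts to
the higher-valued edge.  The blue point is the plain argmax.  All ties
break toward smaller K (parsimony).  One red and one blue point are
marked per subset, so the repetition of an optimum across subsets is
itself the stability signal; the package deliberately does not reduce
the map to a single "best K" — that judgement is left to the user,
though `CommunalMap.suggest_k()` reports the modal red K.

## Core cluster assignments

At a user-chosen (K, subset), the per-algorithm labelings form a
samples × algorithms matrix.  Maximal blocks of samples with identical
label vectors are found; the K−1 largest blocks with distinct
reference-algorithm labels anchor a per-algorithm bijection onto the
reference vocabulary (the K-th correspondence follows by elimination).
Fewer than K−1 usable blocks means the system is under-determined and
the error advises integrating over fewer algorithms; a source label
mapped to two reference labels raises an error naming the offending
algorithm.  After re-keying, each sample takes its modal label when at
least `threshold` (default 50%) of algorithms agree, else 0
(unassigned).  A modal tie is treated as insufficient agreement (0),
which keeps assignment monotone in the threshold.  The reference
algorithm defaults to the first of the retained roster and is
configurable.

Agreement between two labelings is quantified with Goodman–Kruskal's
λ = (Σ_x max_y n_xy − max_y n_·y)/(N − max_y n_·y), always predicting
the labeling with fewer distinct clusters from the other; unassigned
(0) samples are excluded pairwise.

## Synthetic benchmark data

`simdata.simulate` draws K spherical Gaussian components in p
informative dimensions with near-equal sizes (|n_c − n/k| ≤ 1).
Component means are uniform on the unit hypercube; the common
within-component σ is calibrated by root finding so that the mean
pairwise misclassification probability, 2Φ(−d/2σ) for a pair at centre
distance d, equals the requested `overlap`.  The calibration is exact
(closed form for spherical equal-weight components), deterministic
given the seed, and verified to 10⁻⁶ relative error in the tests.
Optional noise variables are i.i.d. N(0,1), independent of cluster
identity; informative variables then have strictly larger marginal
variance than noise variables, so the variance ranking preferentially
fills early subsets with informative variables, as in real expression
data where signal genes are high-variance.

The default overlap is 10⁻⁸.  This is deliberate: in p = 1000
dimensions the pairwise distances concentrate, and cluster structure is
empirically detectable only when the centre separation satisfies
d/σ ≳ √2·p^¼ ≈ 8 (overlap ≲ 10⁻⁴); much larger overlaps (e.g. 10⁻²,
d/σ ≈ 5.2) put every algorithm at near-random partitions and flat
validity curves — a property of high-dimensional geometry, not of any
particular method.  Within the detectable range, the default is the
weakest separation (in decade steps) at which all six benchmark cases
remain identifiable, the generator's stated design requirement: at
d/σ ≈ 11 the K = 3 cases are cleanly recoverable, while K = 7 (smaller
clusters, more component pairs) is borderline — only part of its
subset columns mark the true K and its peaks are the flattest — and
noise variables measurably erode the later subsets.  One decade weaker
(10⁻⁷) the K = 7 cases tip over to a modal optimum of 5–6.  This is
the difficulty gradient the benchmark is meant to exercise.

What the generator does *not* emulate: gene–gene correlation,
heavy-tailed or count-like marginals, batch effects, unequal and
non-spherical component covariances, and cluster structure confined to
a small gene subset.  Passing benchmarks therefore demonstrate correct
mechanics and sensible behaviour on well-posed Gaussian mixtures, not
performance guarantees on real expression data.

## Benchmark harness and problem sizes

The six benchmark cases are K ∈ {3, 5, 7} × {0, 1000} noise variables,
with 300 samples, 1000 informative variables and subsets of step 200
(5 subsets without noise, 10 with).  Per case, the harness records for
every metric the fraction of (algorithm, subset) K-sequences that are
monotone and the fraction with an oriented local maximum at the true K
(edges count only when strictly better than their single neighbour);
per algorithm the tiny-cluster fraction; and for the full pipeline the
red-point K per subset against the truth.  Per-metric numbers are
averaged over cases (matching the published table construction);
overall correctness is the flat fraction over all 45 (case, subset)
columns.  The benchmark uses B = 20 gap replicates and 5 final
metrics, and completes in roughly 10 minutes on one core; B = 50 is
the library default for single analyses.

## Numerical choices and degenerate inputs

- Variance ranking uses the unbiased (N−1) variance; ties keep column
  order.  Missing values are rejected, not imputed.
- `fcluster`/tree cuts that cannot realise all K clusters (duplicate
  points) flag the run as degenerate rather than failing; indices are
  computed on the clusters actually present.
- Gap references with zero dispersion (log 0) are dropped from the
  B-average; data with zero range in every feature is an error.
- Monotonicity needs at least 2 finite values, a red point at least 3
  K values; shorter columns get no red point while blue is still
  computed.
- Z-scoring skips non-finite cells; absent grid cells propagate as
  absences rather than zeros throughout.
- All tie-breaks (peak ties, blue ties, anchor-block ties, stable
  argsorts) resolve toward the smaller index/K, making every stage
  deterministic given the seed.

## Known limitations

- The map is descriptive; no significance is attached to a ridge.
- Re-keying requires K−1 unanimous blocks; very discordant rosters
  fail (by design, with advice to drop algorithms).
- PAM is exact best-improvement SWAP and costs O(N²) per pass; the
  package targets the hundreds-of-samples regime typical of expression
  cohorts, not N ≫ 10⁴.
- Equal-variance spherical simulation understates the heterogeneity of
  real data (see above).
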