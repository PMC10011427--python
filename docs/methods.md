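# Methods

## The selection problem

Given n objects described by p variables of possibly mixed type, the task
is to choose the number of clusters k.  The package's criterion, the
deviation ratio index, is built entirely from the n × k matrix of
dissimilarities between objects and the k *final medoids* of a k-medoids
partition — it never needs the full n × n matrix, and it inherits the
medoid machinery's indifference to the data type: any dissimilarity that
is zero on identical rows, symmetric and non-negative will do.

## BlockD-KM partitioning

The partitioner is a deterministic k-medoids variant.

1. For each object compute the row sum w_i = Σ_l x_il and the sample
   standard deviation u_i of its own p values (p ≥ 2 required).
2. Sort objects ascending by u_i, breaking ties by w_i and then by the
   original index; cut the ordering into *blocks* — maximal runs of
   exactly equal u_i.
3. The first object of each of the first k blocks seeds the k clusters.
   When fewer than k distinct u_i values exist, the first k objects of
   the full ordering are used instead.
4. Assign every object to its nearest medoid.
5. In each cluster, move the medoid to the member with the smallest
   average distance to the cluster's members.
6. Re-assign and recompute SDW(k) = Σ_i d(x_i, m(x_i)), the summed
   distance of objects to their own medoid.
7. Repeat 5–6 until the medoid set stops changing, SDW exactly repeats
   its previous value, or a safety cap (`max_iter`, default 100) is hit;
   the last case is flagged `converged=False` with a warning.

Every tie — sorting, assignment, medoid update — is broken by the lowest
index, so the algorithm is seed-free: a given table and distance always
produce the same partition.  One deliberate guard: during assignment each
medoid is pinned to its own cluster.  With categorical data two distinct
objects can be identical rows; if both are medoids, a zero-distance tie
would otherwise drain the higher-positioned cluster empty.  SDW is
non-increasing across iterations (asserted by tests on every fit).

The row-deviation initialization is cheap and deterministic but
informative mainly when variables are correlated enough that "flat" rows
at different levels sit in different clusters.  With many discrete
variables the initial medoids can land close together; the refinement
loop (which has no swap phase) then carries the burden of spreading them,
and can settle in a local optimum.  This is a property of the algorithm,
not a defect of the implementation, and it shapes the synthetic benchmark
design below.

## Dissimilarities

* **Euclidean** and **Canberra** for numeric rows; Canberra terms with
  both coordinates zero contribute 0 (the standard convention; the sum
  is otherwise undefined).
* **Simple matching distance** for categorical rows: one minus the
  fraction of variables on which two objects agree.
* **Generalized distance (Gower-type)** for mixed rows:
  d = (α·Σ δ_bin + β·Σ δ_cat + γ·Σ δ_num)^ω with mismatch indicators for
  binary and nominal variables and |x − y| on [0, 1]-standardized values
  for numeric variables.  All weights default to 1, making the default a
  plain additive dissimilarity.  Two conventions are explicit package
  choices: the sum is *not* divided by the number of variables (the
  additive form keeps SDW/SDB ratios unchanged anyway, since a constant
  factor cancels in DR), and ordinal variables enter through the numeric
  term after rank scaling z = (r − 1)/(M − 1), not as mismatch
  indicators — rank scaling preserves the ordering information that
  distinguishes an ordinal from a nominal variable.

Numeric columns are min–max standardized to [0, 1] before mixed-type
distances so that per-variable contributions are commensurate.  Constant
numeric columns raise an error rather than mapping silently to zero.
Missing values are rejected at load time; the mixed-data distance is
defined for complete rows only and the package does not impute.

## The deviation ratio index

For a converged k-medoid solution,

* SDW(k) = Σ_i d(x_i, m(x_i)) — within-group deviation,
* SDB(k) = Σ_i Σ_{g ≠ g(i)} d(x_i, m_g) — each object's distances to the
  k − 1 medoids of the *other* groups,
* DR(k) = (SDW/(n − k)) / (SDB/(k − 1)),
* DRI(k) = DR(k)/DR(k + 1).

Degrees-of-freedom scaling mirrors the variance-ratio criterion: as k
grows SDW tends to fall and SDB to rise, so DR falls while genuine
structure is still being resolved and flattens once clusters are being
split needlessly.  The selected k is the smallest with DRI(k) < 1,
equivalently the first k where DR(k) < DR(k + 1).  DR is undefined at
k = 1 (no other group) and when SDB = 0 (all objects coincide with all
medoids); both raise.  When no k in the scanned range qualifies the
selection is reported explicitly as "none in range" rather than coerced.

The default scan covers k = 2..10 in full; an `early_stop` mode halts at
the first DRI(k) < 1, which suffices for the smallest-k rule and saves
the larger fits.

## Comparator criteria

* **Distance-based VRC** (Calinski–Harabasz): VRC = (BGSS/(k − 1)) /
  (WGSS/(n − k)) with WGSS = ½ Σ_g (n_g − 1) d̄_g², BGSS = ½((k − 1) d̄² +
  (n − k) A_k), A_k = Σ_g (n_g − 1)(d̄² − d̄_g²)/(n − k), where d̄² and
  d̄_g² are the overall and within-group mean *squared* pairwise
  dissimilarities.  The squared reading makes the criterion coincide with
  the classical variance-ratio form under Euclidean distance (verified in
  tests against an independent implementation); `squared=False` is
  available for dissimilarities whose square is not meaningful.  WGSS = 0
  returns +inf (perfect separation), and n = k raises.
* **Silhouette**: s(i) = (b − a)/max(a, b); singleton clusters score 0 by
  convention.
* **MSV** (medoid shadow value): (d₂ − d₁)/d₂ from the two closest
  medoids; defined as 0 when d₂ = 0 (object coincident with two
  medoids).  MSV is a diagnostic; its "maximize the mean" k-rule is
  provided for comparison but is not a canonical selection criterion.
* **Clustering accuracy** (external): fraction correct under the best
  one-to-one map of predicted clusters onto true classes, computed by the
  Hungarian algorithm on the contingency table.

## The embedded worked example

The packaged table carries four min–max standardized environmental-health
scores for 25 Asia-Pacific countries at the 2-decimal precision of the
published source.  At k = 3 with Euclidean distance the run selects
initial medoids TLS/JPN/PHL, converges to medoids {TLS, PHL, CHN} with
SDW = 6.71, SDB = 47.03 and DR(3) = 0.0130, and the DRI rule over
k = 2..10 selects three groups.

Two path details are sensitive to the 2-dp rounding of the stored values.
The published source, computed from unrounded data, reaches the same
final solution one medoid step earlier (its group-2 update goes directly
to CHN, while from the rounded values FIJ's within-group mean distance is
smaller by 0.002 for one iteration), and its between-group sum is printed
as 46.9 where the rounded values accumulate to 47.03 over 50 terms.  The
row-deviation and row-sum columns are likewise compared only by ordering,
not by digits, in the tests.

## Synthetic benchmark families

Three families, one per supported data type, each scored by running the
full pipeline (family standardization policy, family distance, BlockD-KM
for k = 2..10, DRI selection) on 50 independently seeded draws; trial t
of base seed s uses seed s + t, so every number is reproducible from the
base seed.

* **categorical** — n = 100, ten binary variables, two equal groups of
  50.  Variable j in group g is Bernoulli(0.8) or Bernoulli(0.2), with
  the high-rate group alternating across variables so that neither group
  is uniformly high.  Distance: simple matching; no standardization.
* **numerical** — n = 150, three equal bivariate standard-normal clusters
  centred at (0, 0), (0, 5) and (5, −3).  Distance: Euclidean on min–max
  standardized columns.
* **mixed** — n = 250, five equal groups on two binary, one 5-level
  ordinal and one numeric variable; Gower distance.  The four distinct
  high/low binary profiles (rates 0.95/0.05) identify four groups and the
  fifth reuses (high, high); the ordinal sits on group modes (1, 3, 5, 2,
  4) with 5% one-level slips; the numeric variable is unit-variance
  normal with means 4 standard deviations apart in the permuted order
  (1, 3, 0, 4, 2).  The two permutations decorrelate the variables from
  the group index: in a design where every variable increases with the
  group, the all-high group's rows are nearly constant, the
  block-deviation initialization then draws *all* k initial medoids from
  that one group, and the swap-free refinement cannot recover — the
  benchmark would measure an initialization pathology rather than the
  criterion.  Binary contrast matters for the same reason: a single
  binary flip costs a full 1.0 in the additive Gower sum, which exceeds
  any between-group numeric gap after min–max scaling (at most ≈ 0.25
  with five groups), so a contrast mild enough to flip frequently caps
  the attainable accuracy of any medoid partition.

Selected-k outcomes are tallied into buckets {≤ k−2, k−1, k, k+1, ≥ k+2};
a "none in range" selection gets its own column (and counts as incorrect
in pooled accuracy), so counts always sum to the number of trials.

What the generators do **not** emulate: unequal cluster sizes, correlated
noise within clusters, outliers, overlapping or non-convex clusters, and
missing data.  Passing recovery benchmarks here therefore demonstrates
that the criterion finds well-separated planted structure of each data
type at these sample sizes — not that it is robust to the messier
geometry of real data, where the choice of standardization and distance
can change the selected k.

## Problem sizes and tolerances

The shipped tests and the acceptance script use the family sizes above
(n = 100–250, 50 trials per family, k scanned 2..10); the full three-
family study runs in a few seconds since each trial reuses one
precomputed pairwise matrix across all k.  Worked-example comparisons use
the printed precision of the embedded 2-dp table (±0.05 on one-decimal
sums, ±0.0005 on DR); internal consistency identities (DR recomputation,
DRI ratio) are checked to 1e−12.  Convergence uses exact float equality
on SDW, with medoid-set equality checked first.

## Known limitations

* BlockD-KM has no swap phase; on data with many discrete variables and
  larger k it can converge to local optima, and the DRI then inherits the
  partition's imperfection (visible in the mixed family's recovery rate).
* The DRI has no distributional theory; it is a heuristic ratio justified
  empirically.
* k = 1 cannot be selected: the index compares partitions, so "no cluster
  structure" must be judged by other means.
* Weights (α, β, γ, ω) other than 1 are supported but untested against
  any external reference.
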