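# Methods

## The semantic model of a taxonomy

`taxaudit` represents a psychometric taxonomy in one vector space. Items are
encoded to embeddings; a scale's embedding is the element-wise **sum** of its
item embeddings, `w_scale = Σ_i w_i`. Because cosine similarity ignores
vector magnitude, summing and averaging item embeddings yield identical
similarities; the sum is used throughout and the equivalence is asserted by
a test. Cluster embeddings (used during relabelling) are means of member
scale embeddings. Label embeddings come in three variants: the bare label
text, the label substituted into the contextualizing template
`"The personality construct [LABEL]."`, and a free-text definition.
Compound labels written `a/b/c` are split on `/`, trimmed, and de-duplicated
case-insensitively (first-seen casing kept); the compound→singles map is
retained so a scale's effective label similarity can take the maximum over
its constituents.

All similarity is cosine. An optional calibration maps cosines onto the
empirical-correlation scale by an affine least-squares fit through anchor
pairs (cosine, mean empirical |r|); with no anchors the map is the identity.
The functional form is a package choice — any monotone map preserves the
rank-based statistics, and an affine map is the simplest that can match a
correlation scale.

### Encoder backends

The default backend is a deterministic stub: each distinct text is hashed
(together with the seed) into a PRNG stream that emits one unit-norm
Gaussian vector of the configured dimension. It is a pure function of
(text, seed, dim), which makes every pipeline stage reproducible and
testable offline. It carries **no semantics**: two paraphrases get unrelated
vectors. Real analyses must use the external sentence-transformer backend;
requesting it without the optional dependency raises an explicit error
rather than falling back silently.

## Validation statistics

- **Predicted internal consistency.** `S̄` is the mean similarity over the
  `N(N−1)/2` unordered distinct item pairs of a scale (self-similarities
  excluded); the Spearman–Brown prophecy formula
  `α̂ = N·S̄ / (1 + (N−1)·S̄)` converts it to a predicted Cronbach's α. The
  empirical counterpart uses the standard variance-ratio estimator on
  listwise-complete response rows.
- **Structural fidelity.** For scale *j* in an inventory with ≥ 3 scales,
  `z_j = (W_j − mean(B_j)) / sd(B_j)`, where `W_j` is the within-scale mean
  item similarity and `B_j` collects the mean cross-scale item similarities
  to every other scale of the same inventory. A scale is *fully recovered*
  at z > 2 and *partially recovered* at z > 1. The ≥ 3 scale restriction is
  what makes the reference standard deviation exist. On empirical
  correlations, the analogue is the ratio of the within mean |r| to the
  strongest mean |r| involving the scale (1 iff within is strongest).
- **Scale–label alignment.** `z = (S_assigned − mean(S_ref)) / sd(S_ref)`
  where `S_l` is the mean similarity of a scale's items to label *l* and the
  reference set is all labels *excluding* the assigned one (≥ 3 required).
  For compound labels the assigned single is the constituent most similar to
  the scale. Alignment scores are averaged across scales, optionally
  restricted to a label subset so different label variants with partial
  coverage can be compared fairly.
- **Prediction error.** Predicted vs observed scale/item correlations are
  compared as MAE and Pearson r over off-diagonal pairs, with observed
  values entered in absolute value (semantic similarity is unsigned).

Conventions used everywhere: sample (n−1) denominators for variances and
standard deviations; pairwise-complete statistics for empirical
correlations; reference spreads below 1e−12 are treated as zero and yield a
flagged *undefined* z rather than a huge finite one.

## Fallacy detection

Detection needs cutoffs saying when two labels are "identical" and when two
scales are "distinct". They follow from assumed bounds on the number of
constructs: with at least `K_min` equally populated constructs, `1/K_min` of
pairs are same-construct, so the `1 − 1/K_min` quantile of the off-diagonal
similarity distribution separates distinct pairs (`K_min = 5` → 0.8); the
upper bound `K_max` gives the identical-pair quantile `1 − 1/K_max`
(`K_max = 100` → 0.99). Realized cutoffs are linear-interpolation empirical
quantiles of the unique unordered off-diagonal similarities, computed
separately for scale and label matrices; degenerate (constant)
distributions are rejected. `ThresholdSet.default()` provides fixed cutoffs
(0.37/0.64 for scales, 0.25/0.50 for labels at the 0.8/0.99 levels, the
conventional values for large personality item pools) for data — such as
zero-noise synthetic taxonomies — whose similarity distribution is
degenerate.

A scale pair is a **jingle** candidate when its label similarity is at or
above the identical-label cutoff while its scale similarity is at or below
the distinct-scale cutoff, and a **jangle** candidate in the converse
configuration. Comparisons are inclusive; because the distinct cutoff lies
below the identical cutoff, the two sets are disjoint. Same-label pairs and
within-inventory pairs are retained (cross-inventory scales of the same
construct can genuinely diverge), and shared-item counts are reported, not
used for exclusion. Raising `K_max` or lowering `K_min` can only shrink the
detected sets — a monotonicity that is tested.

## Taxonomy optimization

Clustering operates on L2-normalized scale embeddings with Euclidean
distance, which is monotone in cosine and keeps the Ward/k-means objectives
well defined. Six algorithms ship: four agglomerative linkages (ward,
single, complete, average), k-means, and spherical-covariance Gaussian
mixtures; mixture fits that return empty components are retried with
documented seed offsets (5 attempts) and rejected afterwards. For each
(algorithm, k) the cluster-mean embeddings are matched one-to-one to labels
by maximum-total-weight rectangular assignment (Hungarian algorithm;
`scipy.optimize.linear_sum_assignment`, whose deterministic output is the
tie-break). Every scale inherits its cluster's label, so same-cluster pairs
have label similarity 1, and the induced mapping is scored with
`detect_fallacies` under thresholds **held fixed across the sweep** —
re-deriving them per solution would make counts incomparable across k. The
sweep flags the global fallacy minimum as *optimal* and the minimum among
solutions with `k ≤ cap` (default 100, mirroring the `K_max` bound) as
*parsimonious*; ties go to the smallest k. Rank diagnostics report, for each
scale, the rank of its assigned label among all labels by cosine (stable
ties) and the fraction assigned a top-5 label.

## Synthetic benchmark

`generate_taxonomy(K, m, p, dim, σ_scale, σ_item, σ_label, seed)` draws K
orthonormalized construct directions (requires `dim ≥ K`; all
between-construct cosines are exactly 0), scatters `m` scale vectors per
construct at noise σ_scale, `p ≥ 2` item vectors per scale at σ_item, and
one label per construct at σ_label, each re-normalized to unit length. `m`
may be a per-construct sequence. At zero noise, within-scale and
within-construct similarities are exactly 1, so ground truth is exact. All
randomness descends from a single seed through named child streams
(directions/scales/items/labels; selection/noise for planting), so every
artifact is bitwise reproducible.

`plant_fallacies` performs label surgery with no side effects: a jingle
planting copies one construct's label (plus σ_label noise) onto **all**
scales of a second, unused construct (ground truth: all m×m cross pairs); a
jangle planting relabels one scale of an unused multi-scale construct with
a label at the **antipode** of its own direction — cosine −1 to its
sibling's label and ≈ 0 to every other label, so no spurious jingle arises
(ground truth: the m−1 sibling pairs). Constructs are never reused and the
planner errors when the requested pair counts are not exactly reachable;
fixtures mix single-scale constructs (jingle hosts) with two-scale
constructs (jangle hosts) to plant any counts exactly. Noise directions are
drawn once per planting from the seed and scaled by σ, which makes each
planted pair's label similarity monotone decreasing in σ_label and hence
detection sensitivity non-increasing along a σ grid.

`generate_responses` turns calibrated item similarities into a target
correlation matrix, repairs it to the nearest valid correlation matrix by
eigenvalue clipping at zero plus diagonal renormalization (the maximum entry
change is recorded and flagged above a tolerance), draws multivariate-normal
respondents, and optionally discretizes the standard-normal margins at
equiprobable quantiles into Likert levels 1..L. Continuous output is the
default for correlation-accuracy tests. The generator emulates only the
correlational structure the pipeline reasons about — it has no acquiescence,
careless responding, item-wording effects, or missingness, and the stub
encoder has no real semantics, so green tests certify the *machinery*
(statistics, detection logic, optimization), not performance on real
inventories, which additionally depends on the quality of the external
encoder.

## Problem sizes and defaults

The shipped tests and the acceptance script run at deliberately small desk
scale, chosen as the smallest sizes at which each property is
non-degenerate: structure recovery uses K = 6 constructs × 3 scales × 8
items in 64 dimensions; fallacy recovery uses K = 15 (ten singleton, five
two-scale constructs) with 5 + 5 planted pairs; reliability recovery uses
exchangeable correlations ρ ∈ {0.1, 0.3, 0.5}, p ∈ {5, 10} items and
n = 2,000 respondents × 100 replicates (tolerance ±0.05, the usual
Monte-Carlo slack for α at that n); matching optimality is verified against
brute-force enumeration for up to 7 clusters × 9 labels over 200 random
instances. The full synthetic pipeline (simulate → detect → optimize)
completes in well under a minute on one CPU at these sizes.

## Known limitations

- The stub encoder validates plumbing, not semantics; conclusions about
  real inventories require the external encoder backend.
- Thresholds assume equally populated constructs; heavily skewed construct
  sizes shift the meaning of the quantile levels.
- Relabelling is sequential (cluster, then match labels); jointly
  optimizing grouping and labelling, eliminating scales, or reassigning
  individual items are out of scope.
- Alignment z-scores require ≥ 3 reference labels and are flagged undefined
  when the reference similarities have (numerically) zero spread.
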