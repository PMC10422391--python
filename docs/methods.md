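# Methods

## The problem and the model

`sleeprec` recommends sleep-pattern configurations to users of sensor
beds.  The central difficulty is that the observed variables — nightly
sleep time, movement events, ambient sound, snoring, plus BMI — are
weakly correlated across users, so no global regression from features to
"good sleep" exists, and new users present a cold-start problem.  The
package's answer has three parts:

1. **Pattern definition.**  Users are clustered in z-scored feature
   space by K-means.  A cluster *is* a sleep pattern; the cluster labels
   SM₁…SM_k form the item catalogue that users rate.
2. **Within-pattern collaborative filtering.**  A user's rating of an
   unrated pattern is predicted as the similarity-weighted mean of the
   ratings given by users with the *same* pattern label.  Restricting
   the neighborhood to the user's cluster is the modelling claim:
   feature-space neighbors are rating-behaviour surrogates.
3. **Feedback.**  Each recommendation round solicits a rating of the
   top-ranked entry and writes it back, so the rating matrix densifies
   and neighborhoods sharpen over time.  Combined with a feature-space
   k-NN fallback this removes the cold-start failure mode: a prediction
   is always defined.

## Procedures and conventions

**Profile aggregation.**  Nightly records are averaged arithmetically
into one 5-vector per user (the aggregation rule is a package choice;
medians would differ only under heavy-tailed sensor noise, which the
generator does not model).  Feedback alters a profile's rating history
only, never its features; repeated feedback on the same pattern
overwrites (latest-wins), keeping the loop responsive.

**Normalization.**  Features are z-scored with population (ddof = 0)
standard deviations.  A constant feature has no meaningful scale and is
rejected by name rather than silently passed through.  All feature-space
distances (clustering, assignment, the k-NN fallback, the content
baseline) are Euclidean in this space.

**K-means.**  k-means++ seeding, Lloyd iterations, best of `restarts`
runs (default 10), convergence when the largest centroid shift falls
below `tol` (default 1e-6) or after `max_iter` (default 300).  These are
the de-facto community defaults; none is sensitive on the benchmark.
Empty clusters are repaired by reseeding at the point farthest from its
assigned centroid, which cannot increase inertia.  The per-assignment
inertia history is exposed and asserted non-increasing in tests.

**Choosing k.**  The elbow curve (inertia vs k over 1..8) is retained as
a diagnostic; the decision is the argmax of mean silhouette over the
candidates where it is defined (k ≥ 2), with ties broken toward the
smaller k.  Singleton clusters score s(i) = 0, as does the degenerate
a = b = 0 case.

**Rating scale.**  Ratings are integers 1–5.  For similarity they are
mapped onto [−1, 1] by r ↦ (r − 3)/2; user–user similarity is the cosine
over co-rated patterns only (pairwise-complete).  Zero-filling missing
entries would manufacture agreement on patterns neither user has seen.
The cosine, not a Euclidean distance, is used on the rating matrix
because only it yields the documented [−1, 1] similarity range; a
ternary {−1, 0, +1} quantization of the matrix is available as a switch.
Pairs with no co-rated pattern, or an all-zero co-rated sub-vector, get
similarity 0 and are excluded from neighbor sets; the neighbor threshold
`tau` defaults to 0 (keep non-negatively similar users).

**Prediction.**  The weighted average runs on raw 1–5 ratings (so
predictions live on the rating scale) with weights from the normalized
matrix.  With all-positive weights the prediction is a convex
combination of neighbor ratings.  Zero similarity mass makes the
prediction undefined, which routes to the fallback: the mean rating of
the `k_nn` (default 5) feature-nearest raters of that pattern from any
cluster, then the global mean rating, then a 3.0 midpoint prior on an
empty matrix.  Final outputs are clipped to [1, 5].

**Baselines.**  `cf` is the same weighted formula without the pattern
restriction and without feedback; its undefined predictions fall back to
item mean → global mean → 3.0 (the feature-space k-NN branch is reserved
for the hybrid engine, whose design it belongs to).  `cbf` predicts
r̂ = clip(5 − β·d(z_u, c_j), 1, 5) with β calibrated by least squares on
the training ratings; because rating columns carry no a-priori position
in feature space, each pattern's centroid c_j is estimated as the
positive-part rating-weighted mean of its raters' features (exact
centroids can be injected for controlled studies).  `cf+cbf` is the
unweighted mean of the two.

**Evaluation.**  Observed ratings are split 80/20 per user (seeded;
users with a single rating stay in training).  MSE = (1/n)Σ(dᵢ − d̂ᵢ)²
and MAPE = (100/n)Σ|dᵢ − d̂ᵢ|/dᵢ; MAPE raises on a zero actual value
(ratings ≥ 1 make this unreachable in normal use).  Accuracy is reported
as 100 − MAPE alongside the raw MAPE to avoid ambiguity.  During the
harness's feedback rounds the simulated user is never asked about a
held-out pair — feedback and held-out ratings are drawn from the same
affinity model, so soliciting a test pair would amount to re-measuring
the answer.  The standalone feedback loop has no such restriction.

## The synthetic benchmark

No public motion-bed rating corpus exists, so the generator plays the
role of the study population, with defaults frozen as the benchmark
conditions: **1000 users** drawn uniformly from **five archetypes**
(settled, short, snoring, restless and long sleepers — means chosen as
physically plausible and mutually well separated in z-space, minimum
centroid separation ≈ 1.7 against a within-cluster spread ≈ 0.35), seven
nights per user, per-night sensor noise, and ratings

    r(u, j) = clip(round(5 − dist(z_u, c_j) + ε), 1, 5),  ε ~ N(0, 0.4)

with each entry missing independently with probability 0.4.  The
affinity model is an explicit stand-in — no public description of how
such users rate exists — chosen because it makes within-cluster CF
informative by construction.  Rounding uses `numpy.rint`
(half-to-even).  `affinity_scale` = 1 spreads ratings over the full 1–5
range at the benchmark's cluster geometry; `rating_noise_sd` = 0.4 makes
±1 rating flips common without drowning the signal.

What passing tests show: the pipeline recovers planted structure
(cluster count and labels), its predictions agree with brute-force
oracles, the hybrid engine beats unrestricted CF *under the generator's
own assumption* that feature clusters govern rating behaviour, and
feedback does not degrade held-out error.  What they do not show:
performance on real sleep data, whose rating process, missingness
mechanism (here: independent uniform) and cluster geometry are unknown;
nor anything about non-Gaussian sensor artifacts, drifting profiles, or
adversarial rating behaviour.

## Problem sizes and runtime choices

The comparison harness uses 10 seeded cohorts of 1000 users with 10
feedback rounds; cluster-count recovery uses 20 seeds; the feedback
trajectory uses 10 seeds × 20 rounds.  These sizes give stable medians
while keeping a full run in the minutes range on one CPU.  Feedback
improvement is asserted as a non-increasing *trend* of the median
trajectory (no round above the pre-feedback baseline, non-positive
rank correlation with round index, final ≤ initial): with stochastic
feedback the trajectory flattens once users have rated every available
pattern, after which medians wiggle by ≲ 0.01 MAPE points around a
constant, so strict pointwise monotonicity is not a meaningful property
of the process.

## Known limitations

* The item catalogue equals the pattern set, so it is small (k ≤ 8);
  the dense rating-matrix representation and O(n·k) similarity rows are
  deliberate and would need sparsification for large catalogues.
* Cluster refitting during the feedback loop is a no-op under the
  current design (feedback never changes features); the hook exists for
  pipelines where profiles evolve.
* `select_k` trusts the silhouette; strongly unbalanced or non-convex
  cluster shapes can mislead it, as for any K-means pipeline.
* The CBF baseline's estimated item centroids shrink toward the
  population mean when a pattern has few enthusiastic raters; β
  calibration absorbs most but not all of that bias.
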