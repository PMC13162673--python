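# Methods

## Setting and assumptions

The package models the decision layer of a semiautomatic plankton-counting
system. Upstream neural components (an object detector and a
metric-learning embedder) are fixed, out-of-scope producers of two
quantities per detected organism: a confidence in [0, 1] and an embedding
vector. The embedder is assumed to have been trained with a cosine-margin
objective, which justifies three modeling assumptions used throughout:

* embeddings live on the unit hypersphere (vectors are re-normalized at
  ingestion rather than trusted, absorbing upstream float drift; a zero
  vector is rejected because its direction is undefined);
* the relevant metric is cosine distance d(u, v) = 1 − u·v ∈ [0, 2]
  (monotone-equivalent to angular distance; we use the linear form);
* same-class embeddings form clusters whose within-class spread is small
  compared to between-class center separation.

The reference index contains only expert-verified records — the training
rule that prevents the system from amplifying its own mistakes. Search is
an exhaustive flat scan, exact by construction; ties in neighbor distance
are broken by ascending object id for reproducibility. Any accelerated
backend would be an optional drop-in required to reproduce the exact
results; none is shipped.

## The cascade

Stages run strictly in order; the first failure routes the object to
review and later stages are not executed (the stage trace records this).
Boundary semantics are strict-below throughout: confidence exactly at the
0.8 gate passes, certainty exactly at the 0.95 threshold auto-accepts.

**KNN proposal.** Among the k = 10 nearest verified vectors, a label
qualifies if it has at least `min_same_label` = 5 representatives and the
aggregated query-to-representative distance (mean by default; median and
max are config options) is strictly below the label's mean intra-label
pairwise distance. k = 10 is the smallest round value for which the
five-of-a-kind condition is non-trivial; both knobs are configurable. If
several labels qualify, the winner has more representatives, then smaller
query distance, then lexicographic order — an arbitrary but deterministic
resolution. A label with fewer than two indexed members has no defined
intra-label mean and can never qualify.

**Cluster membership.** The proposed label's vectors are clustered with
HDBSCAN (scikit-learn implementation) on the precomputed cosine-distance
matrix, `min_cluster_size` = 5, mirroring the proposal stage's count.
Two departures from plain HDBSCAN are deliberate. First, density-based
hierarchies are scale-free, but cosine distance on the sphere is not: a
coherent organism class never has members near-orthogonal to each other.
We therefore impose an absolute density floor `noise_core_distance`
(default 0.5): a point whose core distance (distance to its 5th-nearest
same-label neighbor) exceeds it is declared noise before clustering, and
the same value is used as `cluster_selection_epsilon`, preventing the
known erosion of single-cluster boundaries into noise. Second,
scikit-learn's HDBSCAN has no membership query for unseen points, so we
define one: a query joins the cluster of its nearest clustered training
point iff that distance is within the cluster's largest core distance;
otherwise it is noise. The rule is deterministic and reduces to intuitive
behavior at the extremes (a training member joins its own cluster; a
near-orthogonal query is always noise).

**One-class certainty.** A one-class SVM (RBF kernel, training-outlier
budget ν = 0.05, kernel scale from the median heuristic on pairwise squared
Euclidean distances — on unit vectors these are 2 × cosine distance) is
fitted on the assigned cluster. Raw SVM decision scores have no
interpretable scale, so certainty is obtained by mapping the score through
the interpolated empirical CDF of the training members' own scores,
rescaled piecewise-linearly so that the training ν-quantile lands exactly
at certainty 1 − ν. With the defaults this places the estimator's inlier
boundary exactly at the 0.95 routing threshold: the auto-accept region
coincides with the SVM's own inlier region, typical held-out members score
at or above 0.95, and a far outlier scores near 0. The calibration scores
are cross-fitted (5-fold) whenever the cluster has at least 10 members:
in-sample SVM scores are optimistically shifted, and calibrating on them
makes the empirical CDF under-rate genuinely typical held-out members. The
raw inlier/outlier verdict is available as the `margin` calibration mode.
Degenerate clusters (all vectors identical) still fit, are flagged, and
give certainty 1 at the training point and 0 elsewhere.

Cluster and one-class models are fitted lazily per label and cached; the
cache subscribes to index mutations and drops models for touched labels.

## The active-learning loop

Each round: a batch is triaged; review-routed objects are verified by a
simulated oracle (truth label with probability 1 − error rate, otherwise a
uniformly wrong label); verified records enter the index; models refresh.
"Retraining" means exactly this index-and-model refresh — neural
fine-tuning is out of scope, and the metric-space models are what the
cascade consumes. A seeded 20% slice of each batch is held out for
evaluation and never indexed; retrieval quality on it is reported as
mAP@5: for each query the 5 nearest index records are retrieved, relevance
is label match, average precision is the mean of precision-at-rank over
relevant ranks (0 if none), and mAP is the mean over queries. A
macro-average over classes is not the default reading.

The loop starts from an empty index by default: round 1 routes everything
to review and the reference set bootstraps from oracle verdicts. When no
object is auto-accepted, auto-label accuracy is reported as 0 with
`n_auto` = 0 flagging the vacuous case.

## Agreement statistics

Counts convert to areal abundance (thousand specimens per m²) as
`count / counted_fraction / (π (d/2)²) / 1000` with net mouth diameter
d = 0.375 m.

The permutation test needs care: the naive "L1 distance" statistic
Σᵢ|hᵢ − mᵢ| is invariant under swapping hᵢ with mᵢ within a pair, so a
within-pair permutation test on it is degenerate (every permutation gives
the identical statistic). The non-degenerate reading implemented here
uses T = |Σᵢ(hᵢ − mᵢ)| with a sign-flip null on the per-category
differences. All 2ⁿ flips are enumerated when n ≤ 12 (p is the exact tail
fraction with ties at equality counted); otherwise seeded sampling with
the add-one convention (1 + #{T* ≥ T})/(1 + N). All differences zero
gives p = 1 exactly. Under an exchangeable null the test is calibrated:
the acceptance suite measures a rejection rate of ~0.05 at α = 0.05 over
2000 replicates.

Wilcoxon signed-rank drops zero differences (the original convention;
Pratt available), uses midranks for ties, enumerates the exact sign-flip
null for n ≤ 15, and falls back to the normal approximation with
continuity correction above (via scipy). The exact mode is authored
in-package because scipy's exact path refuses ties. Mann–Whitney delegates
to scipy (exact when nm ≤ 64 and tie-free, tie-corrected normal otherwise).
Bland–Altman works in log2 space with limits at bias ± 2 SD — exactly 2,
not 1.96 — and excludes categories with a zero in either observer rather
than adding pseudocounts, which would silently dominate the limits for
rare taxa; excluded categories are listed. The category breakdown uses
tolerance 0 in raw abundance units by default.

## Synthetic data: what it emulates and what it does not

Class centers are rejection-sampled on the unit sphere with pairwise
cosine separation ≥ 0.5; members are drawn by tangent-space Gaussian
perturbation with per-component SD 1/√κ and renormalization — the
small-angle regime of a von Mises–Fisher distribution, adequate for the
κ ≥ 1 regimes used here (exact vMF sampling was not needed). Defaults:
d = 128, κ = 800, five classes with one dominant class holding 79% of
objects and the rest split evenly, mirroring a strongly copepod-dominated
community. At these values the mean within-class pairwise distance is
(d − 1)/κ ≈ 0.16, about a third of the minimum center separation — a
regime where neighbor lookup is reliable but not trivial. Detector
confidences are Beta(24, 2) (mean ≈ 0.92, a small minority below the 0.8
gate), reflecting a detector that handles most single-organism images.
Novel-class injection places an extra center under the same separation
constraint; drift streams draw per-round batches from scheduled class
mixtures, so a class with zero early weight "arrives" mid-stream. Paired
count tables apply multiplicative lognormal counting noise to both
observers and a per-category machine bias (0.6 for overlap-prone
rotifer-like categories, 1.15 for the dominant category, 1 otherwise);
with all biases 1 the observers are exchangeable, which is the null
configuration the calibration suite uses.

What the generator does *not* emulate: images and their artifacts
(overlapping organisms, chamber scratches, algae interference appear only
abstractly as confidence values and count biases), non-spherical or
heavy-tailed embedding geometry, label noise in the reference index
beyond the oracle's error rate, and seasonal covariate shift beyond
mixture drift. Passing tests therefore demonstrate the correctness and
calibration of the decision layer under its stated geometric assumptions,
not the field performance of any particular embedder.

## Numerical choices and problem sizes

Tolerances: stored norms within 1e-9 of 1; cached intra-label means match
brute-force recomputation to 1e-9; closed-form agreement checks to 1e-9.
Exact-test enumerations use a 1e-12 slack when comparing floating
statistics for tie counting. Determinism: all randomness flows from
`numpy.random.default_rng` seeds; HDBSCAN and the SVM are deterministic
given input order, and label vectors are always presented sorted by object
id. Test and acceptance runs use batches of 120–600 objects, 5–6 classes
and 2000 calibration replicates — sizes chosen so the full suite completes
in seconds while every rate is estimated from hundreds of Bernoulli
trials.

## Known limitations

* The cluster-membership rule is a deterministic approximation, not
  HDBSCAN's soft-membership vector; objects near a cluster boundary may be
  routed to review that soft membership would admit (conservative by
  design).
* Rank calibration makes certainty uniform-ish over the training score
  range; it is a typicality scale, not a posterior probability of class
  membership.
* The exact Wilcoxon enumeration is O(2ⁿ) and capped at n = 15 nonzero
  differences; beyond that the normal approximation is used.
* With fewer than `min_cluster_size` members per label the cascade can
  never auto-accept that label — new classes need a handful of verified
  examples before automation resumes, which is intended behavior.
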