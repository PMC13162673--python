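"""The object-triage cascade: gate, propose, cluster-check, certainty-check.

Every detected object passes through an ordered cascade that decides whether
the machine may label it automatically or whether it must be reviewed by a
human expert:

1. **Detection gate** — objects whose detector confidence is below a
   threshold (default 0.8) go straight to review.
2. **KNN proposal** — the object's embedding is looked up in the verified
   reference index; a label is proposed only if at least ``min_same_label``
   of the ``k_neighbors`` nearest verified vectors share it *and* the mean
   query-to-those-neighbors cosine distance is strictly below the mean
   intra-label distance of that label.
3. **Density-cluster membership** — the proposed label's vectors are
   clustered (hierarchical density-based clustering under cosine distance);
   the object must fall inside one of the clusters, not in noise.
4. **One-class certainty** — a one-class support-vector boundary fitted on
   the assigned cluster scores the object; certainty below the threshold
   (default 0.95) routes it to review.

Only an object that clears every stage is auto-accepted with its proposed
label; any failure, at any stage, makes it a review case.  The cascade is
deliberately conservative: in an open-set monitoring stream a forced wrong
label is worse than an extra expert look.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.svm import OneClassSVM

from .index import ReferenceIndex

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionRecord",
    "TriageParams",
    "StageTrace",
    "TriageDecision",
    "BatchStats",
    "ClusterModel",
    "OneClassModel",
    "ModelCache",
    "detection_gate",
    "propose_label_knn",
    "fit_label_clusters",
    "assign_cluster",
    "fit_one_class",
    "certainty",
    "triage_object",
    "process_batch",
]


@dataclass(frozen=True)
class DetectionRecord:
    """One detector output: a bounding box with a confidence in [0, 1]."""

    object_id: str
    image_id: str
    bbox: tuple[float, float, float, float]  # x_min, y_min, width, height
    confidence: float
    image_extent: tuple[float, float] | None = None  # (width, height) if known

    def __post_init__(self) -> None:
        x, y, w, h = self.bbox
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if x < 0 or y < 0 or w <= 0 or h <= 0:
            raise ValueError(f"invalid bbox {self.bbox}")
        if self.image_extent is not None:
            ew, eh = self.image_extent
            if x + w > ew or y + h > eh:
                raise ValueError(f"bbox {self.bbox} exceeds image extent {self.image_extent}")


@dataclass(frozen=True)
class TriageParams:
    """Tunable knobs of the cascade.

    ``detection_threshold`` and ``certainty_threshold`` follow strict
    "below fails" semantics: a confidence of exactly 0.8 passes the gate and
    a certainty of exactly 0.95 auto-accepts.

    ``k_neighbors`` (how many nearest verified vectors to inspect) is 10 by
    default with ``min_same_label`` 5 — the smallest k for which the
    at-least-5-of-the-same-type condition is non-trivial.

    ``distance_stat`` selects how "distance from these objects" is
    aggregated in the proposal stage (mean by default; median/max offered).

    ``calibration`` selects the certainty scale: ``"rank"`` maps the
    one-class decision score through the training scores' interpolated
    empirical CDF, anchored so the ``svm_nu`` training quantile lands on
    certainty ``1 - svm_nu`` (0.95 at the default budget); ``"margin"``
    uses the estimator's raw inlier/outlier verdict (1 inside, 0 outside).

    ``noise_core_distance`` is an absolute density floor on the unit
    sphere: a point whose core distance (cosine distance to its
    ``min_cluster_size``-th neighbour within the label) exceeds it is
    declared noise before clustering.  Rationale: density clustering alone
    is scale-free, but cosine distance is not — members of a coherent
    organism class are never near-orthogonal to each other, so a core
    distance approaching 0.5 already signals an incoherent neighbourhood.
    """

    detection_threshold: float = 0.8
    k_neighbors: int = 10
    min_same_label: int = 5
    certainty_threshold: float = 0.95
    min_cluster_size: int = 5
    seed: int = 0
    svm_nu: float = 0.05
    calibration: str = "rank"  # or "margin"
    distance_stat: str = "mean"  # or "median", "max"
    noise_core_distance: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.detection_threshold <= 1.0):
            raise ValueError("detection_threshold must be in [0, 1]")
        if not (0.0 <= self.certainty_threshold <= 1.0):
            raise ValueError("certainty_threshold must be in [0, 1]")
        if not (0.0 < self.svm_nu <= 1.0):
            raise ValueError("svm_nu must be in (0, 1]")
        if self.k_neighbors < 1 or self.min_same_label < 1 or self.min_cluster_size < 1:
            raise ValueError("k_neighbors, min_same_label, min_cluster_size must be >= 1")
        if self.min_same_label > self.k_neighbors:
            raise ValueError("min_same_label must be <= k_neighbors")
        if self.calibration not in ("rank", "margin"):
            raise ValueError("calibration must be 'rank' or 'margin'")
        if self.distance_stat not in ("mean", "median", "max"):
            raise ValueError("distance_stat must be one of mean/median/max")


@dataclass
class StageTrace:
    """Per-stage outcome of the cascade for one object.

    A stage is ``"skipped"`` when an earlier stage already failed — the
    cascade never executes a later stage after a failure.
    """

    detection_gate: str = "skipped"  # pass / fail / skipped
    knn_label: str | None = None
    knn_outcome: str = "skipped"  # proposed / none / error / skipped
    knn_query_distance: float | None = None
    knn_intra_label_mean: float | None = None
    cluster_membership: int | str = "skipped"  # cluster id, "noise", "error", "skipped"
    certainty: float | str = "skipped"  # value, "error", "skipped"


@dataclass
class TriageDecision:
    object_id: str
    route: str  # "auto_accept" or "review"
    proposed_label: str | None
    stage_trace: StageTrace

    def __post_init__(self) -> None:
        if self.route not in ("auto_accept", "review"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.route == "auto_accept" and self.proposed_label is None:
            raise ValueError("auto_accept requires a proposed label")


@dataclass
class BatchStats:
    n_objects: int
    n_auto: int
    n_review: int
    auto_fraction: float
    empty_batch: bool
    per_label_auto: dict[str, int]
    stage_failures: dict[str, int]


# --------------------------------------------------------------------------
# stage 1: detection gate


def detection_gate(det: DetectionRecord, params: TriageParams) -> bool:
    """True iff the detection passes the confidence gate (strict below fails)."""
    return det.confidence >= params.detection_threshold


# --------------------------------------------------------------------------
# stage 2: KNN label proposal


def propose_label_knn(
    index: ReferenceIndex, query: np.ndarray, params: TriageParams
) -> tuple[str, dict] | None:
    """Propose a label from the k-nearest verified neighbors, or ``None``.

    A label qualifies when (a) at least ``min_same_label`` of the k nearest
    neighbors carry it, and (b) the aggregated query-to-those-neighbors
    cosine distance is strictly below the label's mean intra-label distance.
    If several labels qualify, the one with more representatives wins, then
    the smaller query distance, then lexicographic order.
    """
    neighbors = index.knn_search(query, params.k_neighbors)
    by_label: dict[str, list[float]] = {}
    for _oid, label, dist in neighbors:
        by_label.setdefault(label, []).append(dist)

    agg = {"mean": np.mean, "median": np.median, "max": np.max}[params.distance_stat]
    qualifying: list[tuple[int, float, str, float]] = []
    for label, dists in by_label.items():
        if len(dists) < params.min_same_label:
            continue
        qdist = float(agg(dists))
        try:
            intra = index.mean_intra_label_distance(label)
        except ValueError:
            logger.info("label %r has <2 members; cannot qualify", label)
            continue
        if qdist < intra:
            qualifying.append((-len(dists), qdist, label, intra))
    if not qualifying:
        return None
    qualifying.sort()
    neg_n, qdist, label, intra = qualifying[0]
    return label, {
        "query_distance": qdist,
        "intra_label_mean": intra,
        "n_representatives": -neg_n,
    }


# --------------------------------------------------------------------------
# stage 3: density-cluster membership


class ClusterModel:
    """Density clustering of one label's vectors with membership queries.

    Fitted with hierarchical density-based clustering (HDBSCAN) on the
    precomputed cosine-distance matrix; points whose core distance exceeds
    ``noise_core_distance`` are pre-declared noise (see
    :class:`TriageParams`).  A new point joins the cluster of its nearest
    clustered training point iff its distance to that point is within the
    cluster's largest core distance; otherwise it is noise.
    """

    def __init__(self, vectors: np.ndarray, assignments: np.ndarray, params: TriageParams):
        self.vectors = vectors
        self.assignments = assignments  # -1 = noise
        self.params = params
        self._cluster_eps: dict[int, float] = {}
        k = min(params.min_cluster_size, len(vectors) - 1)
        dmat = 1.0 - vectors @ vectors.T
        np.fill_diagonal(dmat, np.inf)
        core = np.sort(dmat, axis=1)[:, k - 1] if k >= 1 else np.zeros(len(vectors))
        for cid in self.cluster_ids:
            mask = assignments == cid
            self._cluster_eps[cid] = float(np.max(core[mask]))

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(int(c) for c in set(self.assignments) if c >= 0)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def noise_fraction(self) -> float:
        return float(np.mean(self.assignments < 0))

    def assign(self, query: np.ndarray) -> int | str:
        """Cluster id the query would join, or ``"noise"``."""
        clustered = self.assignments >= 0
        if not clustered.any():
            return "noise"
        dists = 1.0 - self.vectors[clustered] @ np.asarray(query, dtype=np.float64)
        cids = self.assignments[clustered]
        best = int(np.argmin(dists))
        cid = int(cids[best])
        if float(dists[best]) <= self._cluster_eps[cid]:
            return cid
        return "noise"


def fit_label_clusters(
    index: ReferenceIndex, label: str, params: TriageParams
) -> ClusterModel:
    """Cluster one label's verified vectors under cosine distance."""
    vectors = index.vectors_for_label(label)
    n = vectors.shape[0]
    if n < params.min_cluster_size:
        raise ValueError(
            f"label {label!r} has {n} members; need >= {params.min_cluster_size} "
            "to cluster — route the object to review"
        )
    dmat = 1.0 - vectors @ vectors.T
    np.clip(dmat, 0.0, None, out=dmat)
    np.fill_diagonal(dmat, 0.0)
    # absolute density floor: near-orthogonal neighbourhoods are noise
    with_diag_inf = dmat.copy()
    np.fill_diagonal(with_diag_inf, np.inf)
    k = min(params.min_cluster_size, n - 1)
    core = np.sort(with_diag_inf, axis=1)[:, k - 1]
    dense = core <= params.noise_core_distance
    assignments = np.full(n, -1, dtype=int)
    n_dense = int(dense.sum())
    if n_dense >= params.min_cluster_size:
        sub = dmat[np.ix_(dense, dense)]
        clusterer = HDBSCAN(
            min_cluster_size=params.min_cluster_size,
            metric="precomputed",
            allow_single_cluster=True,
            # cosine distance has an absolute scale on the sphere: links
            # shorter than the density floor never erode into noise
            cluster_selection_epsilon=params.noise_core_distance,
            copy=True,
        )
        sub_labels = clusterer.fit_predict(sub)
        assignments[dense] = sub_labels
    return ClusterModel(vectors, assignments, params)


def assign_cluster(model: ClusterModel, query: np.ndarray) -> int | str:
    """Membership query against a fitted cluster model."""
    return model.assign(query)


# --------------------------------------------------------------------------
# stage 4: one-class certainty


class OneClassModel:
    """One-class support-vector boundary with a calibrated certainty scale.

    The raw signed decision score of a one-class SVM has no interpretable
    scale, but the routing threshold (0.95) implies a probability-like one.
    In ``"rank"`` mode the score is mapped through the interpolated
    empirical CDF of (cross-fitted) training-member scores, rescaled so the
    training ``nu``-quantile falls exactly on certainty ``1 - nu``.  With
    the defaults (``nu`` = 0.05, threshold 0.95) a point at the estimator's
    inlier boundary scores exactly at the routing threshold, so the
    auto-accept region coincides with the SVM's own inlier region, while a
    stricter or looser threshold remains a meaningful dial.  In ``"margin"``
    mode certainty is the raw inlier verdict (1 inside, 0 outside).
    """

    def __init__(self, vectors: np.ndarray, params: TriageParams):
        n = vectors.shape[0]
        if n < params.min_cluster_size:
            raise ValueError(
                f"one-class fit needs >= {params.min_cluster_size} vectors, got {n}"
            )
        self.params = params
        sq = np.maximum(2.0 * (1.0 - vectors @ vectors.T), 0.0)
        iu = np.triu_indices(n, k=1)
        med = float(np.median(sq[iu]))
        self.degenerate = med < 1e-12
        gamma = 1.0 / med if not self.degenerate else 1.0
        self.svm = OneClassSVM(kernel="rbf", nu=params.svm_nu, gamma=gamma)
        self.svm.fit(vectors)
        # calibration scores are cross-fitted when possible: in-sample
        # decision scores are optimistically shifted, so an empirical CDF
        # built from them under-rates typical held-out members
        if n >= 10 and not self.degenerate:
            rng = np.random.default_rng(params.seed)
            perm = rng.permutation(n)
            folds = np.array_split(perm, 5)
            scores = np.empty(n)
            for fold in folds:
                mask = np.ones(n, dtype=bool)
                mask[fold] = False
                svm_f = OneClassSVM(kernel="rbf", nu=params.svm_nu, gamma=gamma)
                svm_f.fit(vectors[mask])
                scores[fold] = svm_f.decision_function(vectors[fold])
            self._train_scores = np.sort(scores)
        else:
            self._train_scores = np.sort(self.svm.decision_function(vectors))

    def certainty(self, query: np.ndarray) -> float:
        q = np.asarray(query, dtype=np.float64).reshape(1, -1)
        score = float(self.svm.decision_function(q)[0])
        if self.params.calibration == "margin":
            return 1.0 if score >= 0.0 else 0.0
        return self._rank_calibrate(score)

    def _rank_calibrate(self, score: float) -> float:
        s = self._train_scores
        n = len(s)
        if s[-1] - s[0] < 1e-15:  # degenerate: all training scores equal
            return 1.0 if score >= s[0] - 1e-12 else 0.0
        cdf = float(np.interp(score, s, np.arange(1, n + 1) / n, left=0.0, right=1.0))
        nu = self.params.svm_nu
        # anchor: the training nu-quantile maps to certainty 1 - nu, so with
        # nu = 0.05 a point at the estimator's inlier boundary scores exactly
        # 0.95 — the routing threshold coincides with the SVM's own budget
        if cdf < nu:
            return (1.0 - nu) * cdf / nu
        return (1.0 - nu) + nu * (cdf - nu) / (1.0 - nu)


def fit_one_class(cluster_vectors: np.ndarray, params: TriageParams) -> OneClassModel:
    """Fit the one-class boundary estimator on a cluster's vectors."""
    return OneClassModel(np.asarray(cluster_vectors, dtype=np.float64), params)


def certainty(model: OneClassModel, query: np.ndarray) -> float:
    """Calibrated typicality of ``query`` for the model's cluster, in [0, 1]."""
    return model.certainty(query)


# --------------------------------------------------------------------------
# model cache


class ModelCache:
    """Lazily fitted, mutation-invalidated per-label cluster and SVM models."""

    def __init__(self, index: ReferenceIndex, params: TriageParams):
        self.index = index
        self.params = params
        self._clusters: dict[str, ClusterModel] = {}
        self._oneclass: dict[tuple[str, int], OneClassModel] = {}
        index.add_mutation_hook(self._invalidate)

    def _invalidate(self, touched_labels: set[str]) -> None:
        for lab in touched_labels:
            self._clusters.pop(lab, None)
            for key in [k for k in self._oneclass if k[0] == lab]:
                self._oneclass.pop(key)

    def cluster_model(self, label: str) -> ClusterModel:
        if label not in self._clusters:
            self._clusters[label] = fit_label_clusters(self.index, label, self.params)
        return self._clusters[label]

    def one_class_model(self, label: str, cluster_id: int) -> OneClassModel:
        key = (label, cluster_id)
        if key not in self._oneclass:
            model = self._clusters[label]
            vecs = model.vectors[model.assignments == cluster_id]
            self._oneclass[key] = fit_one_class(vecs, self.params)
        return self._oneclass[key]


# --------------------------------------------------------------------------
# the cascade


def triage_object(
    index: ReferenceIndex,
    det: DetectionRecord,
    embedding: np.ndarray,
    params: TriageParams,
    cache: ModelCache | None = None,
) -> TriageDecision:
    """Run the full cascade on one object; never leaves it unrouted."""
    trace = StageTrace()

    if not detection_gate(det, params):
        trace.detection_gate = "fail"
        return TriageDecision(det.object_id, "review", None, trace)
    trace.detection_gate = "pass"

    try:
        proposal = propose_label_knn(index, embedding, params)
    except ValueError:  # e.g. empty index
        trace.knn_outcome = "error"
        return TriageDecision(det.object_id, "review", None, trace)
    if proposal is None:
        trace.knn_outcome = "none"
        return TriageDecision(det.object_id, "review", None, trace)
    label, diag = proposal
    trace.knn_outcome = "proposed"
    trace.knn_label = label
    trace.knn_query_distance = diag["query_distance"]
    trace.knn_intra_label_mean = diag["intra_label_mean"]

    try:
        cmodel = (
            cache.cluster_model(label)
            if cache is not None
            else fit_label_clusters(index, label, params)
        )
    except ValueError:
        trace.cluster_membership = "error"
        return TriageDecision(det.object_id, "review", label, trace)
    membership = assign_cluster(cmodel, embedding)
    trace.cluster_membership = membership
    if membership == "noise":
        return TriageDecision(det.object_id, "review", label, trace)

    try:
        ocm = (
            cache.one_class_model(label, int(membership))
            if cache is not None
            else fit_one_class(cmodel.vectors[cmodel.assignments == membership], params)
        )
    except ValueError:
        trace.certainty = "error"
        return TriageDecision(det.object_id, "review", label, trace)
    cert = ocm.certainty(embedding)
    trace.certainty = cert
    route = "auto_accept" if cert >= params.certainty_threshold else "review"
    return TriageDecision(det.object_id, route, label, trace)


def process_batch(
    index: ReferenceIndex,
    objects: Sequence[tuple[DetectionRecord, np.ndarray]],
    params: TriageParams,
    cache: ModelCache | None = None,
) -> tuple[list[TriageDecision], list[TriageDecision], BatchStats]:
    """Triage a batch; every object lands in exactly one of the two queues."""
    if cache is None and len(index) > 0:
        cache = ModelCache(index, params)
    auto: list[TriageDecision] = []
    review: list[TriageDecision] = []
    per_label_auto: dict[str, int] = {}
    stage_failures = {
        "detection_gate": 0,
        "knn_proposal": 0,
        "cluster_membership": 0,
        "certainty": 0,
    }
    for det, emb in objects:
        dec = triage_object(index, det, emb, params, cache)
        if dec.route == "auto_accept":
            auto.append(dec)
            per_label_auto[dec.proposed_label] = per_label_auto.get(dec.proposed_label, 0) + 1
        else:
            review.append(dec)
            t = dec.stage_trace
            if t.detection_gate == "fail":
                stage_failures["detection_gate"] += 1
            elif t.knn_outcome in ("none", "error"):
                stage_failures["knn_proposal"] += 1
            elif t.cluster_membership in ("noise", "error"):
                stage_failures["cluster_membership"] += 1
            else:
                stage_failures["certainty"] += 1
    n = len(objects)
    stats = BatchStats(
        n_objects=n,
        n_auto=len(auto),
        n_review=len(review),
        auto_fraction=(len(auto) / n) if n else 0.0,
        empty_batch=n == 0,
        per_label_auto=per_label_auto,
        stage_failures=stage_failures,
    )
    return auto, review, stats
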