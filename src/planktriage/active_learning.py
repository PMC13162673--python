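"""Simulated human-in-the-loop rounds over a streamed sample series.

Each round mirrors the operational loop of the monitoring system: a batch
of detected objects is triaged against the current verified reference
index; everything routed to review is "shown" to a (simulated) expert
oracle; the oracle's verified labels are appended to the index; all
metric-space models are refreshed; and retrieval quality plus the
auto-processed fraction are tracked round over round.

"Retraining" here means refreshing the reference index and refitting the
per-label cluster / one-class models the cascade consumes — the embedder
itself is a fixed upstream component.  A held-out slice of each batch
(never added to the index) provides the evaluation set for mAP@5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .index import EmbeddingRecord, ReferenceIndex
from .synthetic import StreamObject
from .triage import ModelCache, TriageDecision, TriageParams, process_batch

__all__ = [
    "ReviewQueue",
    "RoundMetrics",
    "simulate_oracle",
    "map_at_5",
    "update_round",
    "run_active_loop",
]


@dataclass
class ReviewQueue:
    """Review-routed decisions paired with their unverified records, in stream order."""

    pending: list[tuple[TriageDecision, EmbeddingRecord]]

    def __post_init__(self) -> None:
        for dec, _rec in self.pending:
            if dec.route != "review":
                raise ValueError(f"object {dec.object_id} is not review-routed")

    def __len__(self) -> int:
        return len(self.pending)


@dataclass
class RoundMetrics:
    """Quality and throughput figures for one loop round."""

    round_id: int
    auto_fraction: float
    auto_label_accuracy: float  # 0.0 (flagged by n_auto=0) when nothing auto-accepted
    map_at_5: float
    queue_size: int
    index_size: int
    n_auto: int = 0
    n_objects: int = 0


def simulate_oracle(
    queue: ReviewQueue,
    truth: dict[str, str],
    error_rate: float = 0.0,
    seed: int = 0,
    label_pool: list[str] | None = None,
) -> list[EmbeddingRecord]:
    """Stand-in for the human expert verifying the review queue.

    Each queued object receives its ground-truth label with probability
    ``1 - error_rate``, otherwise a uniformly random *wrong* label from the
    pool.  All returned records are verified.  Deterministic given seed.
    """
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    missing = [dec.object_id for dec, _ in queue.pending if dec.object_id not in truth]
    if missing:
        raise ValueError(f"no truth label for queued objects: {missing[:5]}")
    pool = sorted(set(label_pool if label_pool is not None else truth.values()))
    rng = np.random.default_rng(seed)
    out: list[EmbeddingRecord] = []
    for dec, rec in queue.pending:
        label = truth[dec.object_id]
        if error_rate > 0 and rng.random() < error_rate:
            wrong = [p for p in pool if p != label]
            if wrong:
                label = wrong[rng.integers(len(wrong))]
        out.append(replace(rec, label=label, verified=True))
    return out


def map_at_5(index: ReferenceIndex, eval_set: list[EmbeddingRecord]) -> float:
    """Mean average precision over the top-5 retrieved neighbors.

    For each labeled evaluation embedding the 5 nearest index records are
    retrieved; relevance is label match.  Average precision for one query
    is the mean of precision-at-rank over the relevant ranks (0 when no
    retrieved record is relevant); mAP@5 is the mean over queries.
    """
    if not eval_set:
        raise ValueError("evaluation set is empty")
    if len(index) == 0:
        raise ValueError("index is empty")
    overlap = [r.object_id for r in eval_set if r.object_id in index]
    if overlap:
        raise ValueError(f"evaluation records already indexed: {overlap[:5]}")
    aps = []
    for rec in eval_set:
        if rec.label is None:
            raise ValueError(f"evaluation record {rec.object_id} has no label")
        neighbors = index.knn_search(rec.vector, 5)
        rel = [nb_label == rec.label for _oid, nb_label, _d in neighbors]
        hits = 0
        precisions = []
        for rank, is_rel in enumerate(rel, start=1):
            if is_rel:
                hits += 1
                precisions.append(hits / rank)
        aps.append(float(np.mean(precisions)) if precisions else 0.0)
    return float(np.mean(aps))


def update_round(
    index: ReferenceIndex,
    queue: ReviewQueue,
    oracle_out: list[EmbeddingRecord],
    params: TriageParams,
    eval_set: list[EmbeddingRecord] | None = None,
    round_id: int = 0,
    batch_stats=None,
    auto_decisions: list[TriageDecision] | None = None,
    truth: dict[str, str] | None = None,
) -> RoundMetrics:
    """Fold verified records into the index and emit round metrics.

    ``add_verified`` notifies the mutation hooks, so any
    :class:`~planktriage.triage.ModelCache` registered on the index drops
    its cluster / one-class models for the touched labels.
    """
    index.add_verified(oracle_out)
    n_auto = len(auto_decisions or [])
    n_objects = batch_stats.n_objects if batch_stats is not None else n_auto + len(queue)
    accuracy = 0.0
    if auto_decisions and truth:
        correct = sum(
            1 for d in auto_decisions if d.proposed_label == truth.get(d.object_id)
        )
        accuracy = correct / n_auto
    map5 = 0.0
    if eval_set and len(index) > 0:
        map5 = map_at_5(index, eval_set)
    return RoundMetrics(
        round_id=round_id,
        auto_fraction=(batch_stats.auto_fraction if batch_stats is not None else 0.0),
        auto_label_accuracy=accuracy,
        map_at_5=map5,
        queue_size=len(queue),
        index_size=len(index),
        n_auto=n_auto,
        n_objects=n_objects,
    )


def run_active_loop(
    stream: list[list[StreamObject]],
    params: TriageParams,
    n_rounds: int | None = None,
    oracle_error_rate: float = 0.0,
    seed: int = 0,
    initial_index: ReferenceIndex | None = None,
    eval_fraction: float = 0.2,
) -> tuple[list[RoundMetrics], ReferenceIndex]:
    """Run the full loop: triage, verify, retrain, measure — per round.

    Starts from an empty index by default, so round 1 routes everything to
    review and bootstraps the reference set from oracle verdicts.  A seeded
    20% slice of each batch is held out for mAP@5 evaluation and never
    enters the index.
    """
    if n_rounds is None:
        n_rounds = len(stream)
    if n_rounds < 1 or n_rounds > len(stream):
        raise ValueError("n_rounds must be in [1, len(stream)]")
    if not all(stream[:n_rounds]):
        raise ValueError("stream batches must be non-empty")
    dim = stream[0][0].vector.shape[0]
    index = initial_index if initial_index is not None else ReferenceIndex(dim=dim)
    cache = ModelCache(index, params)
    ss = np.random.SeedSequence(seed)
    round_seeds = ss.generate_state(2 * n_rounds) % (2**31)
    metrics: list[RoundMetrics] = []
    for r in range(n_rounds):
        batch = stream[r]
        rng = np.random.default_rng(round_seeds[2 * r])
        n_eval = int(round(eval_fraction * len(batch)))
        eval_idx = set(rng.choice(len(batch), size=n_eval, replace=False).tolist())
        eval_set = [
            EmbeddingRecord(
                object_id=obj.object_id,
                sample_id=f"round_{r:02d}",
                vector=obj.vector,
                label=obj.truth_label,
                verified=True,
                timestamp=obj.timestamp,
            )
            for i, obj in enumerate(batch)
            if i in eval_idx
        ]
        work = [obj for i, obj in enumerate(batch) if i not in eval_idx]
        truth = {obj.object_id: obj.truth_label for obj in work}
        auto, review, stats = process_batch(
            index, [(obj.detection, obj.vector) for obj in work], params, cache
        )
        rec_by_id = {
            obj.object_id: EmbeddingRecord(
                object_id=obj.object_id,
                sample_id=f"round_{r:02d}",
                vector=obj.vector,
                label=None,
                verified=False,
                timestamp=obj.timestamp,
            )
            for obj in work
        }
        queue = ReviewQueue([(dec, rec_by_id[dec.object_id]) for dec in review])
        oracle_out = simulate_oracle(
            queue, truth, error_rate=oracle_error_rate, seed=int(round_seeds[2 * r + 1])
        )
        metrics.append(
            update_round(
                index,
                queue,
                oracle_out,
                params,
                eval_set=eval_set,
                round_id=r,
                batch_stats=stats,
                auto_decisions=auto,
                truth=truth,
            )
        )
    return metrics, index
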