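"""Unit-norm embedding records and an exact cosine-similarity flat index.

Classification in this system is metric-space retrieval: every detected
object is a 128-dimensional unit vector produced by a metric-learning
embedder, and label proposals come from exact k-nearest-neighbor lookup
under cosine distance ``1 - u.v``.  The :class:`ReferenceIndex` is the
searchable store of *verified* labeled embeddings — only records confirmed
by a human expert ever enter it — together with a cache of mean intra-label
pairwise distances, which the triage heuristics compare query distances
against.

The search is an exhaustive flat scan: every query is compared against every
stored vector, so results are exact by construction.  Any accelerated
backend would have to reproduce these results bit-for-bit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingRecord",
    "ReferenceIndex",
    "normalize",
    "cosine_distance",
]

#: L2-norm tolerance for stored vectors.
NORM_TOL = 1e-9


def normalize(v: Sequence[float] | np.ndarray) -> np.ndarray:
    """Return ``v`` scaled to unit L2 norm, direction preserved.

    Raises
    ------
    ValueError
        If ``v`` is (numerically) the zero vector: its direction is
        undefined and no cosine comparison is possible.
    """
    arr = np.asarray(v, dtype=np.float64)
    nrm = float(np.linalg.norm(arr))
    if nrm == 0.0 or not np.isfinite(nrm):
        raise ValueError("cannot normalize a zero or non-finite vector")
    return arr / nrm


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance ``1 - u.v`` between two unit vectors, in [0, 2]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(1.0 - u @ v)


@dataclass(frozen=True)
class EmbeddingRecord:
    """One detected object's embedding vector with optional label.

    Parameters
    ----------
    object_id : str
        Opaque identifier, unique within an index.
    sample_id : str
        The water sample (net haul) the object came from.
    vector : ndarray
        Embedding; re-normalized to unit L2 norm at construction rather
        than trusted, to absorb upstream float drift.
    label : str or None
        Category name (species / developmental stage), if known.
    verified : bool
        True only when a human expert has confirmed the label.
    timestamp : int
        Ordinal position in the sample stream (>= 0).
    """

    object_id: str
    sample_id: str
    vector: np.ndarray
    label: str | None = None
    verified: bool = False
    timestamp: int = 0

    def __post_init__(self) -> None:
        vec = normalize(self.vector)
        vec.setflags(write=False)
        object.__setattr__(self, "vector", vec)
        if self.verified and self.label is None:
            raise ValueError(
                f"record {self.object_id!r}: verified records must carry a label"
            )
        if self.timestamp < 0:
            raise ValueError(f"record {self.object_id!r}: timestamp must be >= 0")


class ReferenceIndex:
    """Exact flat index over verified labeled embeddings.

    Stores only records with ``verified=True`` (the training-data rule of
    the continuous-adaptation loop) and exposes exhaustive cosine-distance
    k-NN search plus cached per-label mean intra-label distances.
    """

    def __init__(self, dim: int = 128) -> None:
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = int(dim)
        self._records: dict[str, EmbeddingRecord] = {}
        self._matrix: np.ndarray | None = None  # row-aligned with _order
        self._order: list[str] = []
        self._intra_cache: dict[str, float] = {}
        # listeners notified with the set of labels touched by a mutation
        self._mutation_hooks: list = []

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, object_id: str) -> bool:
        return object_id in self._records

    def __iter__(self):
        return iter(self._records.values())

    @property
    def labels(self) -> list[str]:
        """Sorted list of distinct labels present."""
        return sorted({r.label for r in self._records.values()})

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self._records.values():
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def records_for_label(self, label: str) -> list[EmbeddingRecord]:
        return [r for r in self._records.values() if r.label == label]

    def vectors_for_label(self, label: str) -> np.ndarray:
        recs = sorted(self.records_for_label(label), key=lambda r: r.object_id)
        if not recs:
            return np.empty((0, self.dim))
        return np.stack([r.vector for r in recs])

    # -- mutation ------------------------------------------------------------

    def add_verified(self, records: Iterable[EmbeddingRecord]) -> "ReferenceIndex":
        """Add verified records; reject unverified ones with a warning.

        Duplicate ``object_id`` (against the index or within the batch) is an
        error.  Per-label distance caches for every touched label are
        invalidated, and registered mutation hooks are notified so dependent
        models (cluster / one-class caches) can refresh.
        """
        accepted: list[EmbeddingRecord] = []
        seen_new: set[str] = set()
        for rec in records:
            if not rec.verified or rec.label is None:
                warnings.warn(
                    f"rejecting unverified record {rec.object_id!r}: only "
                    "expert-verified records may enter the reference index",
                    stacklevel=2,
                )
                logger.warning("rejected unverified record %s", rec.object_id)
                continue
            if rec.object_id in self._records or rec.object_id in seen_new:
                raise ValueError(f"duplicate object_id {rec.object_id!r}")
            if rec.vector.shape != (self.dim,):
                raise ValueError(
                    f"record {rec.object_id!r}: dimension "
                    f"{rec.vector.shape[0]} != index dim {self.dim}"
                )
            seen_new.add(rec.object_id)
            accepted.append(rec)

        for rec in accepted:
            self._records[rec.object_id] = rec
        if accepted:
            touched = {r.label for r in accepted}
            self._matrix = None
            for lab in touched:
                self._intra_cache.pop(lab, None)
            for hook in self._mutation_hooks:
                hook(touched)
        return self

    def add_mutation_hook(self, hook) -> None:
        """Register ``hook(touched_labels: set[str])`` called on every mutation."""
        self._mutation_hooks.append(hook)

    # -- search --------------------------------------------------------------

    def _ensure_matrix(self) -> None:
        if self._matrix is None:
            self._order = sorted(self._records)  # ascending id = tie-break order
            self._matrix = (
                np.stack([self._records[i].vector for i in self._order])
                if self._order
                else np.empty((0, self.dim))
            )

    def knn_search(
        self, query: np.ndarray, k: int
    ) -> list[tuple[str, str, float]]:
        """Exact k-nearest neighbors of ``query`` under cosine distance.

        Returns ``min(k, len(index))`` tuples ``(object_id, label, distance)``
        sorted by ascending distance, ties broken by ascending ``object_id``.
        """
        if len(self._records) == 0:
            raise ValueError("knn_search on an empty index")
        if k < 1:
            raise ValueError("k must be >= 1")
        query = np.asarray(query, dtype=np.float64)
        if query.shape != (self.dim,):
            raise ValueError(f"query dimension {query.shape} != ({self.dim},)")
        self._ensure_matrix()
        dists = 1.0 - self._matrix @ query
        # stable ordering on (distance, object_id); _order is already id-sorted
        # so a stable sort by distance realizes the tie-break.
        idx = np.argsort(dists, kind="stable")[: min(k, len(self._order))]
        return [
            (self._order[i], self._records[self._order[i]].label, float(dists[i]))
            for i in idx
        ]

    # -- per-label statistics --------------------------------------------------

    def mean_intra_label_distance(self, label: str) -> float:
        """Mean cosine distance over all unordered pairs of ``label`` members.

        Cached; the cache is invalidated whenever a mutation touches the
        label.  Undefined (error) below two members — the proposal heuristic
        must then treat the label as non-qualifying.
        """
        if label in self._intra_cache:
            return self._intra_cache[label]
        vecs = self.vectors_for_label(label)
        n = vecs.shape[0]
        if n < 2:
            raise ValueError(
                f"mean intra-label distance undefined for label {label!r} "
                f"with {n} member(s); need >= 2"
            )
        gram = vecs @ vecs.T
        iu = np.triu_indices(n, k=1)
        val = float(np.mean(1.0 - gram[iu]))
        self._intra_cache[label] = val
        return val
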