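"""Seeded generators for every synthetic input the pipeline consumes.

Real inputs to the triage system are (a) 128-dimensional unit-norm
embeddings of detected organisms, which form per-class clusters on the
hypersphere because the embedder was trained with a cosine-margin loss;
(b) detector confidences; and (c) paired human/machine abundance tables.
This module emulates all three, fully seeded:

* class centers sampled on the unit sphere with a minimum pairwise cosine
  separation (rejection sampling);
* members drawn by Gaussian perturbation in the tangent space at the
  center with per-component SD ``1/sqrt(kappa)``, then renormalized — the
  small-angle regime of a von Mises-Fisher distribution with concentration
  ``kappa``;
* novel-class injection (a cluster absent from the reference index);
* a drifting sample stream whose per-round class mixture follows a
  schedule, so later rounds can introduce classes unseen earlier;
* paired count tables with category-specific machine bias — the machine
  undercounting overlap-prone rotifer-like categories and overcounting the
  dominant copepod-like category.

The default composition mirrors a strongly dominated community: one class
holding ~79% of objects and the remainder split evenly, which is what a
late-summer net sample from a copepod-dominated lake looks like.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .agreement import NET_MOUTH_DIAMETER_M, PairedAbundanceTable, counts_to_areal
from .index import EmbeddingRecord, normalize
from .triage import DetectionRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticEmbeddings",
    "StreamObject",
    "default_class_weights",
    "default_category_bias",
    "generate_embeddings",
    "inject_novel_class",
    "generate_drift_stream",
    "generate_paired_counts",
]

_MAX_CENTER_ATTEMPTS = 10_000


def default_class_weights(n_classes: int, dominant: float = 0.79) -> tuple[float, ...]:
    """One dominant class, the rest of the mass split evenly."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if n_classes == 1:
        return (1.0,)
    rest = (1.0 - dominant) / (n_classes - 1)
    return (dominant,) + (rest,) * (n_classes - 1)


def default_category_bias(categories) -> dict[str, float]:
    """Category-specific machine counting bias.

    Rotifer-like categories (name contains ``rotifer``) are undercounted
    (organisms overlap in the images); the dominant copepod-like category
    (name contains ``dominant`` or listed first) is overcounted slightly.
    """
    cats = list(categories)
    bias = {}
    for i, c in enumerate(cats):
        lc = c.lower()
        if "rotifer" in lc:
            bias[c] = 0.6
        elif "dominant" in lc or i == 0:
            bias[c] = 1.15
        else:
            bias[c] = 1.0
    return bias


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    ``kappa`` is the directional concentration: members of a class scatter
    around its center with tangent-space SD ``1/sqrt(kappa)`` per
    component, giving a mean within-class pairwise cosine distance of about
    ``(dim - 1) / kappa``.  The default (dim 128, kappa 800) puts the
    within-class spread near 0.16 while centers are kept at least 0.5
    apart — separation roughly three times the spread, the regime in which
    neighbor lookup is reliable but not trivially so.
    """

    dim: int = 128
    n_classes: int = 5
    n_objects: int = 300
    kappa: float = 800.0
    min_separation: float = 0.5
    novel_fraction: float = 0.0
    class_weights: tuple[float, ...] | None = None
    drift_schedule: tuple[dict[str, float], ...] | None = None
    batch_size: int = 200
    confidence_alpha: float = 24.0
    confidence_beta: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not (0.0 < self.min_separation < 2.0):
            raise ValueError("min_separation must be in (0, 2)")
        if not (0.0 <= self.novel_fraction < 1.0):
            raise ValueError("novel_fraction must be in [0, 1)")
        if self.class_weights is not None:
            w = tuple(float(x) for x in self.class_weights)
            if len(w) != self.n_classes:
                raise ValueError("class_weights length must equal n_classes")
            if abs(sum(w) - 1.0) > 1e-9 or any(x < 0 for x in w):
                raise ValueError("class_weights must be non-negative and sum to 1")
            object.__setattr__(self, "class_weights", w)
        if self.drift_schedule is not None:
            sched = tuple(dict(rnd) for rnd in self.drift_schedule)
            for rnd in sched:
                if abs(sum(rnd.values()) - 1.0) > 1e-9:
                    raise ValueError("each round's mixture weights must sum to 1")
            object.__setattr__(self, "drift_schedule", sched)

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(f"class_{i:02d}" for i in range(self.n_classes))

    @property
    def weights(self) -> tuple[float, ...]:
        if self.class_weights is not None:
            return self.class_weights
        return default_class_weights(self.n_classes)


@dataclass
class SyntheticEmbeddings:
    """Generated records plus the ground truth needed to score the pipeline."""

    records: list[EmbeddingRecord]
    truth: dict[str, str]  # object_id -> generating class
    centers: dict[str, np.ndarray]  # class name -> unit center
    novel_labels: frozenset[str] = frozenset()
    config: SyntheticConfig | None = None


@dataclass(frozen=True)
class StreamObject:
    """One object of a streamed batch: detection + embedding + truth."""

    object_id: str
    detection: DetectionRecord
    vector: np.ndarray
    truth_label: str
    timestamp: int


# --------------------------------------------------------------------------


def _sample_centers(
    rng: np.random.Generator,
    n: int,
    dim: int,
    min_separation: float,
    existing: list[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Rejection-sample unit centers with pairwise cosine distance >= min_separation."""
    centers: list[np.ndarray] = list(existing or [])
    n_existing = len(centers)
    attempts = 0
    while len(centers) < n_existing + n:
        if attempts >= _MAX_CENTER_ATTEMPTS:
            raise RuntimeError(
                f"could not place {n} centers with separation "
                f">= {min_separation} in dim {dim}; use fewer classes or a "
                "lower separation"
            )
        attempts += 1
        cand = normalize(rng.standard_normal(dim))
        if all(1.0 - cand @ c >= min_separation for c in centers):
            centers.append(cand)
    return centers[n_existing:]


def _sample_members(
    rng: np.random.Generator, center: np.ndarray, n: int, kappa: float
) -> np.ndarray:
    """Tangent-space Gaussian perturbation + renormalization around a center."""
    dim = center.shape[0]
    g = rng.standard_normal((n, dim)) / np.sqrt(kappa)
    g -= np.outer(g @ center, center)  # project onto tangent space
    members = center[None, :] + g
    return members / np.linalg.norm(members, axis=1, keepdims=True)


def _apportion(total: int, weights) -> list[int]:
    """Largest-remainder apportionment of ``total`` by ``weights``."""
    raw = np.asarray(weights, dtype=np.float64) * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base.tolist()


def draw_class_members(center, n: int, kappa: float, seed: int = 0) -> np.ndarray:
    """Draw ``n`` fresh members around an existing class center.

    Used to produce query or held-out sets that share the geometry of an
    already generated class without re-rolling its center.
    """
    rng = np.random.default_rng(seed)
    return _sample_members(rng, normalize(center), n, kappa)


def generate_embeddings(
    config: SyntheticConfig, id_prefix: str = "obj", verified: bool = True
) -> SyntheticEmbeddings:
    """Generate per-class clustered unit embeddings; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    centers = _sample_centers(rng, config.n_classes, config.dim, config.min_separation)
    names = config.class_names
    sizes = _apportion(config.n_objects, config.weights)
    records: list[EmbeddingRecord] = []
    truth: dict[str, str] = {}
    t = 0
    for name, center, size in zip(names, centers, sizes):
        vecs = _sample_members(rng, center, size, config.kappa)
        for v in vecs:
            oid = f"{id_prefix}_{t:05d}"
            records.append(
                EmbeddingRecord(
                    object_id=oid,
                    sample_id="sample_00",
                    vector=v,
                    label=name if verified else None,
                    verified=verified,
                    timestamp=t,
                )
            )
            truth[oid] = name
            t += 1
    result = SyntheticEmbeddings(
        records=records,
        truth=truth,
        centers=dict(zip(names, centers)),
        config=config,
    )
    if config.novel_fraction > 0:
        result = inject_novel_class(result, config)
    return result


def inject_novel_class(
    data: SyntheticEmbeddings, config: SyntheticConfig, label: str = "novel_00"
) -> SyntheticEmbeddings:
    """Add a cluster from a class absent from the known set.

    The novel center respects the separation constraint against every
    existing center; the ground truth marks its members with ``label`` and
    the label is recorded in ``novel_labels``.  ``novel_fraction`` is the
    share of the *final* record set that is novel.
    """
    if config.novel_fraction == 0.0:
        return data
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6E]))
    existing = list(data.centers.values())
    (center,) = _sample_centers(rng, 1, config.dim, config.min_separation, existing)
    n_existing = len(data.records)
    n_novel = round(config.novel_fraction / (1.0 - config.novel_fraction) * n_existing)
    vecs = _sample_members(rng, center, n_novel, config.kappa)
    t0 = max((r.timestamp for r in data.records), default=-1) + 1
    records = list(data.records)
    truth = dict(data.truth)
    for i, v in enumerate(vecs):
        oid = f"novel_{t0 + i:05d}"
        records.append(
            EmbeddingRecord(
                object_id=oid,
                sample_id="sample_00",
                vector=v,
                label=None,
                verified=False,
                timestamp=t0 + i,
            )
        )
        truth[oid] = label
    centers = dict(data.centers)
    centers[label] = center
    return SyntheticEmbeddings(
        records=records,
        truth=truth,
        centers=centers,
        novel_labels=data.novel_labels | {label},
        config=config,
    )


def _draw_confidences(rng: np.random.Generator, n: int, config: SyntheticConfig) -> np.ndarray:
    return rng.beta(config.confidence_alpha, config.confidence_beta, size=n)


def generate_drift_stream(config: SyntheticConfig) -> list[list[StreamObject]]:
    """Ordered batches drawn from the per-round scheduled class mixtures.

    Every class named anywhere in the schedule must exist in the config's
    class set; classes with zero weight in early rounds simply do not
    appear there, which is how a novel class "arrives" mid-stream.
    """
    if config.drift_schedule is None:
        raise ValueError("config.drift_schedule must be provided")
    known = set(config.class_names)
    for rnd in config.drift_schedule:
        unknown = set(rnd) - known
        if unknown:
            raise ValueError(f"drift schedule references undefined classes: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    centers = dict(
        zip(
            config.class_names,
            _sample_centers(rng, config.n_classes, config.dim, config.min_separation),
        )
    )
    stream: list[list[StreamObject]] = []
    t = 0
    for round_id, mixture in enumerate(config.drift_schedule):
        cats = sorted(mixture)
        weights = np.array([mixture[c] for c in cats])
        counts = rng.multinomial(config.batch_size, weights)
        batch: list[StreamObject] = []
        for cat, cnt in zip(cats, counts):
            if cnt == 0:
                continue
            vecs = _sample_members(rng, centers[cat], cnt, config.kappa)
            confs = _draw_confidences(rng, cnt, config)
            for v, conf in zip(vecs, confs):
                oid = f"r{round_id:02d}_obj_{t:05d}"
                det = DetectionRecord(
                    object_id=oid,
                    image_id=f"img_{t:05d}",
                    bbox=(0.0, 0.0, 64.0, 64.0),
                    confidence=float(conf),
                )
                batch.append(StreamObject(oid, det, v, cat, t))
                t += 1
        # stream order within a round is randomized so classes interleave
        order = rng.permutation(len(batch))
        stream.append([batch[i] for i in order])
    return stream


def generate_paired_counts(
    truth_counts: dict[str, float],
    bias: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    counted_fraction: float = 1.0,
    net_mouth_diameter_m: float = NET_MOUTH_DIAMETER_M,
) -> PairedAbundanceTable:
    """Paired human/machine abundance from true per-category counts.

    Human counts are the truth with multiplicative lognormal counting noise
    (SD ``noise_sd`` on the log scale); machine counts additionally carry a
    per-category multiplicative bias (< 1 undercounting, > 1 overcounting).
    With ``bias`` all 1 and ``noise_sd`` 0 the two observers are identical;
    with biases 1 and noise > 0 they are exchangeable, which is the null
    configuration used to calibrate the permutation test.  Both series are
    converted to thousand specimens per m² via the net-mouth geometry.
    """
    cats = list(truth_counts)
    if bias is None:
        bias = {c: 1.0 for c in cats}
    missing = set(cats) - set(bias)
    if missing:
        raise ValueError(f"bias missing for categories: {sorted(missing)}")
    if any(b <= 0 for b in bias.values()):
        raise ValueError("bias factors must be > 0")
    if any(v < 0 for v in truth_counts.values()):
        raise ValueError("truth counts must be >= 0")
    rng = np.random.default_rng(seed)
    human = []
    machine = []
    for c in cats:
        tval = truth_counts[c]
        h_noise = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
        m_noise = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
        human.append(
            counts_to_areal(tval * h_noise, counted_fraction, net_mouth_diameter_m)
        )
        machine.append(
            counts_to_areal(tval * bias[c] * m_noise, counted_fraction, net_mouth_diameter_m)
        )
    return PairedAbundanceTable(tuple(cats), np.array(human), np.array(machine))
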