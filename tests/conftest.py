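"""Shared fixtures: small deterministic indexes and clustered sphere data."""

import numpy as np
import pytest

from planktriage.index import EmbeddingRecord, ReferenceIndex, normalize
from planktriage.synthetic import draw_class_members


def random_unit_vectors(rng, n, dim):
    return np.array([normalize(v) for v in rng.standard_normal((n, dim))])


def make_records(vectors, label=None, verified=False, prefix="obj", sample="s0", t0=0):
    return [
        EmbeddingRecord(
            object_id=f"{prefix}_{i:04d}",
            sample_id=sample,
            vector=v,
            label=label,
            verified=verified,
            timestamp=t0 + i,
        )
        for i, v in enumerate(vectors)
    ]


def build_index(by_label: dict, dim: int) -> ReferenceIndex:
    """Index from {label: vectors-array}; ids are '<label>_<i>'."""
    idx = ReferenceIndex(dim=dim)
    for label, vecs in by_label.items():
        idx.add_verified(make_records(vecs, label=label, verified=True, prefix=label))
    return idx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_class_index(rng):
    """Two tight well-separated classes (d=32) plus their centers."""
    dim = 32
    a = normalize(rng.standard_normal(dim))
    b = normalize(rng.standard_normal(dim))
    b = normalize(b - (b @ a) * a)  # orthogonal to a
    vec_a = draw_class_members(a, 30, kappa=2000.0, seed=1)
    vec_b = draw_class_members(b, 30, kappa=2000.0, seed=2)
    idx = build_index({"alpha": vec_a, "beta": vec_b}, dim)
    return idx, {"alpha": a, "beta": b}
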