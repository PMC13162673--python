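"""The triage cascade: gate, KNN proposal, cluster filter, certainty filter."""

import dataclasses

import numpy as np
import pytest

from planktriage.index import EmbeddingRecord, ReferenceIndex, normalize
from planktriage.synthetic import draw_class_members
from planktriage.triage import (
    DetectionRecord,
    ModelCache,
    TriageParams,
    assign_cluster,
    detection_gate,
    fit_label_clusters,
    fit_one_class,
    process_batch,
    propose_label_knn,
    triage_object,
)

from conftest import build_index, random_unit_vectors


def det(oid="q", conf=0.95):
    return DetectionRecord(oid, "img", (0.0, 0.0, 10.0, 10.0), conf)


def orthonormal_pair(rng, dim):
    a = normalize(rng.standard_normal(dim))
    b = normalize(rng.standard_normal(dim))
    return a, normalize(b - (b @ a) * a)


PARAMS = TriageParams()


class TestDetectionGate:
    @pytest.mark.parametrize(
        "conf,passes", [(0.79, False), (0.80, True), (1.0, True), (0.0, False)]
    )
    def test_strictly_below_threshold_fails(self, conf, passes):
        assert detection_gate(det(conf=conf), PARAMS) is passes


class TestProposeLabelKnn:
    def test_tight_majority_class_proposed(self, rng):
        a, b = orthonormal_pair(rng, 16)
        idx = build_index(
            {
                "aaa": draw_class_members(a, 6, kappa=5000.0, seed=1),
                "bbb": draw_class_members(b, 3, kappa=5000.0, seed=2),
            },
            16,
        )
        out = propose_label_knn(idx, a, PARAMS)
        assert out is not None and out[0] == "aaa"
        label, diag = out
        assert diag["query_distance"] < diag["intra_label_mean"]

    def test_too_few_same_label_neighbors(self, rng):
        a, b = orthonormal_pair(rng, 16)
        # only 4 'aaa' members exist; min_same_label=5 cannot be met
        idx = build_index(
            {
                "aaa": draw_class_members(a, 4, kappa=5000.0, seed=1),
                "bbb": draw_class_members(b, 6, kappa=5000.0, seed=2),
            },
            16,
        )
        assert propose_label_knn(idx, a, PARAMS) is None

    def test_distant_query_not_proposed(self, rng):
        a = normalize(rng.standard_normal(16))
        idx = build_index({"aaa": draw_class_members(a, 8, kappa=5000.0, seed=1)}, 16)
        far = normalize(np.ones(16) - (np.ones(16) @ a) * a)  # orthogonal to a
        assert propose_label_knn(idx, far, PARAMS) is None

    def test_single_member_label_cannot_qualify(self, rng):
        params = dataclasses.replace(PARAMS, k_neighbors=1, min_same_label=1)
        a = normalize(rng.standard_normal(16))
        idx = build_index({"aaa": a[None, :]}, 16)
        assert propose_label_knn(idx, a, params) is None


class TestClusterStage:
    def test_single_tight_cluster_no_noise(self, rng):
        a = normalize(rng.standard_normal(128))
        idx = build_index({"aaa": draw_class_members(a, 20, kappa=1e4, seed=1)}, 128)
        model = fit_label_clusters(idx, "aaa", PARAMS)
        assert model.n_clusters == 1
        assert model.noise_fraction == 0.0

    def test_two_separated_clusters(self, rng):
        a, b = orthonormal_pair(rng, 128)
        vecs = np.vstack(
            [
                draw_class_members(a, 10, kappa=1e4, seed=1),
                draw_class_members(b, 10, kappa=1e4, seed=2),
            ]
        )
        idx = build_index({"aaa": vecs}, 128)
        assert fit_label_clusters(idx, "aaa", PARAMS).n_clusters == 2

    def test_uniform_sphere_is_noise(self, rng):
        vecs = random_unit_vectors(rng, 20, 128)
        idx = build_index({"aaa": vecs}, 128)
        model = fit_label_clusters(idx, "aaa", PARAMS)
        assert model.noise_fraction >= 0.8

    def test_too_few_members_errors(self, rng):
        idx = build_index({"aaa": random_unit_vectors(rng, 3, 16)}, 16)
        with pytest.raises(ValueError, match="review"):
            fit_label_clusters(idx, "aaa", PARAMS)

    def test_membership_of_member_centroid_and_far_point(self, rng):
        a = normalize(rng.standard_normal(128))
        vecs = draw_class_members(a, 20, kappa=1e4, seed=1)
        idx = build_index({"aaa": vecs}, 128)
        model = fit_label_clusters(idx, "aaa", PARAMS)
        member_cluster = model.assignments[0]
        assert assign_cluster(model, vecs[0]) == member_cluster
        assert assign_cluster(model, normalize(vecs.mean(axis=0))) == member_cluster
        far = normalize(rng.standard_normal(128))
        assert assign_cluster(model, far) == "noise"


class TestOneClassStage:
    def test_in_sample_mostly_inside(self, rng):
        a = normalize(rng.standard_normal(64))
        vecs = draw_class_members(a, 50, kappa=3000.0, seed=3)
        model = fit_one_class(vecs, PARAMS)
        inside = np.mean([model.certainty(v) >= 0.95 for v in vecs])
        assert inside >= 0.9

    def test_minimum_and_below_minimum_sizes(self, rng):
        a = normalize(rng.standard_normal(16))
        fit_one_class(draw_class_members(a, 5, kappa=3000.0, seed=1), PARAMS)
        with pytest.raises(ValueError, match=">= 5"):
            fit_one_class(draw_class_members(a, 4, kappa=3000.0, seed=1), PARAMS)

    def test_degenerate_identical_vectors_still_fits(self):
        v = normalize(np.arange(1.0, 9.0))
        model = fit_one_class(np.stack([v] * 6), PARAMS)
        assert model.degenerate
        assert model.certainty(v) == 1.0

    def test_medoid_above_threshold_far_query_below_half(self, rng):
        a = normalize(rng.standard_normal(64))
        vecs = draw_class_members(a, 50, kappa=3000.0, seed=4)
        model = fit_one_class(vecs, PARAMS)
        medoid = vecs[np.argmax((vecs @ vecs.T).sum(axis=0))]
        assert model.certainty(medoid) >= 0.95
        far = normalize(rng.standard_normal(64))
        assert 1.0 - abs(float(far @ a)) > 0.5  # genuinely far
        assert model.certainty(far) < 0.5

    def test_certainty_codomain(self, rng):
        a = normalize(rng.standard_normal(32))
        model = fit_one_class(draw_class_members(a, 30, kappa=3000.0, seed=5), PARAMS)
        for v in random_unit_vectors(rng, 20, 32):
            assert 0.0 <= model.certainty(v) <= 1.0


class TestTriageObject:
    def test_gate_failure_skips_later_stages(self, two_class_index):
        idx, centers = two_class_index
        dec = triage_object(idx, det(conf=0.5), centers["alpha"], PARAMS)
        assert dec.route == "review"
        t = dec.stage_trace
        assert t.detection_gate == "fail"
        assert t.knn_outcome == "skipped"
        assert t.cluster_membership == "skipped"
        assert t.certainty == "skipped"

    def test_centroid_of_known_class_auto_accepted(self, two_class_index):
        idx, centers = two_class_index
        dec = triage_object(idx, det(), centers["alpha"], PARAMS)
        assert dec.route == "auto_accept"
        assert dec.proposed_label == "alpha"
        assert dec.stage_trace.certainty >= 0.95

    def test_far_query_reviewed_with_no_proposal(self, two_class_index, rng):
        idx, _ = two_class_index
        far = normalize(np.concatenate([np.zeros(31), [1.0]]) + rng.normal(0, 1e-3, 32))
        dec = triage_object(idx, det(), far, PARAMS)
        assert dec.route == "review"
        assert dec.stage_trace.knn_outcome in ("none", "proposed")
        if dec.stage_trace.knn_outcome == "proposed":
            assert dec.stage_trace.cluster_membership == "noise"

    def test_empty_index_routes_review_not_crash(self):
        idx = ReferenceIndex(dim=8)
        dec = triage_object(idx, det(), normalize(np.ones(8)), PARAMS)
        assert dec.route == "review"
        assert dec.stage_trace.knn_outcome == "error"

    def test_cascade_never_runs_stage_after_failure(self, two_class_index, rng):
        """Stage trace ordering: once a stage fails, later ones stay skipped."""
        idx, centers = two_class_index
        order = ["detection_gate", "knn", "cluster", "certainty"]
        for q, conf in [
            (centers["alpha"], 0.1),
            (random_unit_vectors(rng, 1, 32)[0], 0.95),
            (centers["beta"], 0.95),
        ]:
            t = triage_object(idx, det(conf=conf), q, PARAMS).stage_trace
            states = [
                t.detection_gate != "skipped",
                t.knn_outcome != "skipped",
                t.cluster_membership != "skipped",
                t.certainty != "skipped",
            ]
            # executed stages form a prefix
            assert states == sorted(states, reverse=True)


class TestProcessBatch:
    def test_empty_batch(self, two_class_index):
        idx, _ = two_class_index
        auto, review, stats = process_batch(idx, [], PARAMS)
        assert auto == [] and review == []
        assert stats.auto_fraction == 0.0 and stats.empty_batch

    def test_all_gate_failures(self, two_class_index, rng):
        idx, _ = two_class_index
        objs = [
            (det(f"q{i}", 0.1), random_unit_vectors(rng, 1, 32)[0]) for i in range(10)
        ]
        auto, review, stats = process_batch(idx, objs, PARAMS)
        assert stats.auto_fraction == 0.0
        assert stats.stage_failures["detection_gate"] == 10

    def test_conservation(self, two_class_index, rng):
        idx, centers = two_class_index
        objs = []
        for i in range(30):
            q = (
                draw_class_members(centers["alpha"], 1, 2000.0, seed=100 + i)[0]
                if i % 2
                else random_unit_vectors(rng, 1, 32)[0]
            )
            objs.append((det(f"q{i}", float(rng.uniform(0.5, 1.0))), q))
        auto, review, stats = process_batch(idx, objs, PARAMS)
        ids = sorted(d.object_id for d in auto) + sorted(d.object_id for d in review)
        assert len(auto) + len(review) == 30
        assert sorted(ids) == sorted(f"q{i}" for i in range(30))

    def test_mixed_batch_rates(self, two_class_index, rng):
        """Typical members of known classes mostly auto; novel mostly review."""
        idx, centers = two_class_index
        known = np.vstack(
            [
                draw_class_members(centers["alpha"], 75, 2000.0, seed=11),
                draw_class_members(centers["beta"], 75, 2000.0, seed=12),
            ]
        )
        novel_center = normalize(rng.standard_normal(32))
        # keep the novel center away from both known centers
        while min(
            1 - novel_center @ centers["alpha"], 1 - novel_center @ centers["beta"]
        ) < 0.5:
            novel_center = normalize(rng.standard_normal(32))
        novel = draw_class_members(novel_center, 50, 2000.0, seed=13)
        objs = [(det(f"k{i}"), v) for i, v in enumerate(known)]
        objs += [(det(f"n{i}"), v) for i, v in enumerate(novel)]
        auto, review, stats = process_batch(idx, objs, PARAMS)
        review_novel = sum(1 for d in review if d.object_id.startswith("n"))
        assert review_novel >= 45  # >= 90% of novels reviewed
        assert 0.6 <= stats.auto_fraction <= 0.85


class TestMonotonicity:
    def test_raising_certainty_threshold_never_adds_autos(self, two_class_index, rng):
        idx, centers = two_class_index
        queries = np.vstack(
            [
                draw_class_members(centers["alpha"], 20, 2000.0, seed=21),
                random_unit_vectors(rng, 10, 32),
            ]
        )
        objs = [(det(f"q{i}"), v) for i, v in enumerate(queries)]
        previous_autos = None
        for thr in (0.5, 0.8, 0.95, 0.99, 1.0):
            params = dataclasses.replace(PARAMS, certainty_threshold=thr)
            auto, _, _ = process_batch(idx, objs, params)
            autos = {d.object_id for d in auto}
            if previous_autos is not None:
                assert autos <= previous_autos
            previous_autos = autos


class TestModelCache:
    def test_cache_invalidated_on_index_mutation(self, two_class_index):
        idx, centers = two_class_index
        cache = ModelCache(idx, PARAMS)
        m1 = cache.cluster_model("alpha")
        assert cache.cluster_model("alpha") is m1  # cached
        new = draw_class_members(centers["alpha"], 3, 2000.0, seed=77)
        idx.add_verified(
            [
                EmbeddingRecord(f"new_{i}", "s", v, "alpha", True)
                for i, v in enumerate(new)
            ]
        )
        m2 = cache.cluster_model("alpha")
        assert m2 is not m1
        assert m2.vectors.shape[0] == m1.vectors.shape[0] + 3
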