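import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phannot.datasets import split_clusters
from phannot.io import ClusterMap, EmbeddingMatrix
from phannot.models import (
    CalibratedSVC,
    PredictionRecord,
    assign_from_confidences,
    top_confidence,
    train_binary,
)
from phannot.ontology import Category, Ontology


@pytest.fixture(scope="module")
def chain_ontology():
    return Ontology([
        Category("pvp", min_train_clusters=0),
        Category("tail", parent="pvp", min_train_clusters=0),
        Category("fiber", parent="tail", min_train_clusters=0),
        Category("lysis", min_train_clusters=0),
    ])


def _separable_dataset(seed=0, n=200, dim=16):
    """Two Gaussian blobs 10 sigma apart; any margin classifier is perfect."""
    from phannot.datasets import CategoryDataset
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack([
        rng.standard_normal((half, dim)) + 10.0,
        rng.standard_normal((n - half, dim)),
    ])
    ids = [f"p{i}" for i in range(n)]
    clusters = ClusterMap({pid: f"c{i % 40}" if i < half else f"c{40 + i % 40}"
                           for i, pid in enumerate(ids)})
    split = split_clusters(clusters, 0.8, seed=seed)
    ds = CategoryDataset(
        category="pvp",
        positives=set(ids[:half]),
        negatives=set(ids[half:]),
        excluded=set(),
        split=split,
        clusters=clusters,
    )
    return ds, EmbeddingMatrix(ids, X)


class TestTrainBinary:
    def test_separable_blobs_are_learned(self):
        ds, emb = _separable_dataset()
        model = train_binary(ds, emb, random_state=0)
        test_ids = ds.test_positives() + ds.test_negatives()
        conf = model.confidence(emb.matrix_for(test_ids))
        truth = np.array([pid in ds.positives for pid in test_ids])
        accuracy = ((conf >= 0.5) == truth).mean()
        assert accuracy >= 0.99

    def test_single_class_rejected(self):
        ds, emb = _separable_dataset()
        ds.negatives, ds.excluded = set(), ds.negatives
        with pytest.raises(ValueError, match="class"):
            train_binary(ds, emb)

    def test_same_seed_identical_probe_output(self):
        ds, emb = _separable_dataset()
        probe = emb.vectors[:25]
        a = train_binary(ds, emb, random_state=5).confidence(probe)
        b = train_binary(ds, emb, random_state=5).confidence(probe)
        np.testing.assert_array_equal(a, b)

    def test_missing_embeddings_raise(self):
        ds, emb = _separable_dataset()
        small = EmbeddingMatrix(emb.ids[:10], emb.vectors[:10])
        with pytest.raises(KeyError):
            train_binary(ds, small)

    def test_probabilities_in_unit_interval(self):
        ds, emb = _separable_dataset()
        conf = train_binary(ds, emb).confidence(emb.vectors)
        assert np.all((conf >= 0.0) & (conf <= 1.0))


class TestCalibratedSVC:
    def test_single_class_fit_rejected(self):
        est = CalibratedSVC()
        with pytest.raises(ValueError, match="single class"):
            est.fit(np.random.default_rng(0).standard_normal((10, 3)), np.ones(10))

    def test_sklearn_get_set_params(self):
        est = CalibratedSVC(C=2.0)
        assert est.get_params()["C"] == 2.0
        est.set_params(C=0.5)
        assert est.C == 0.5

    def test_standardize_option_trains_and_scores(self):
        rng = np.random.default_rng(3)
        n = 200
        y = np.repeat([0, 1], n // 2)
        # wildly different feature scales: standardization must cope
        X = rng.standard_normal((n, 3)) * np.array([1e-3, 1.0, 1e3])
        X[y == 1] += np.array([5e-3, 5.0, 5e3])
        est = CalibratedSVC(standardize=True, random_state=0).fit(X, y)
        assert (est.predict(X) == y).mean() >= 0.95

    def test_weak_monotone_calibration(self):
        """High-confidence bins must be purer than mid-confidence bins."""
        rng = np.random.default_rng(1)
        n = 600
        y = rng.integers(0, 2, n)
        # overlapping blobs: confidence spectrum is populated
        X = rng.standard_normal((n, 4)) + 1.2 * y[:, None]
        est = CalibratedSVC(random_state=0).fit(X[:400], y[:400])
        conf = est.confidence(X[400:])
        truth = y[400:]
        hi = truth[(conf >= 0.9)]
        mid = truth[(conf >= 0.5) & (conf < 0.6)]
        assert len(hi) and len(mid)
        assert hi.mean() > mid.mean()


class TestGating:
    def test_child_requires_parent(self, chain_ontology):
        got = assign_from_confidences(
            {"pvp": 0.4, "tail": 0.9}, chain_ontology, 0.5
        )
        assert got == set()

    def test_assignment_is_ancestor_closed(self, chain_ontology):
        got = assign_from_confidences(
            {"pvp": 0.9, "tail": 0.7, "fiber": 0.8, "lysis": 0.2}, chain_ontology, 0.5
        )
        assert got == {"pvp", "tail", "fiber"}

    def test_threshold_095_shrinks_assignment(self, chain_ontology):
        conf = {"pvp": 0.96, "tail": 0.7, "lysis": 0.2}
        assert assign_from_confidences(conf, chain_ontology, 0.95) == {"pvp"}
        assert assign_from_confidences(conf, chain_ontology, 0.5) == {"pvp", "tail"}

    @settings(max_examples=200, deadline=None)
    @given(data=st.data())
    def test_gating_soundness_random_tables(self, chain_ontology, data):
        """Child assigned => parent assigned; unknown <=> nothing assigned."""
        cats = [c.name for c in chain_ontology]
        evaluated = {
            c: data.draw(st.floats(min_value=0.0, max_value=1.0))
            for c in cats
            if data.draw(st.booleans())
        }
        t = data.draw(st.floats(min_value=0.01, max_value=0.99))
        assigned = assign_from_confidences(evaluated, chain_ontology, t)
        for c in assigned:
            parent = chain_ontology.categories[c].parent
            assert parent is None or parent in assigned
            assert evaluated[c] >= t
        unknown = not assigned
        assert unknown == (len(assigned) == 0)

    @settings(max_examples=100, deadline=None)
    @given(data=st.data())
    def test_threshold_monotonicity(self, chain_ontology, data):
        cats = [c.name for c in chain_ontology]
        evaluated = {
            c: data.draw(st.floats(min_value=0.0, max_value=1.0)) for c in cats
        }
        t1 = data.draw(st.floats(min_value=0.01, max_value=0.98))
        t2 = data.draw(st.floats(min_value=t1, max_value=0.99))
        a1 = assign_from_confidences(evaluated, chain_ontology, t1)
        a2 = assign_from_confidences(evaluated, chain_ontology, t2)
        assert a2 <= a1
        if not a1:
            assert not a2  # raising t never makes an unknown protein known


class TestTopConfidence:
    def test_picks_highest_level(self, chain_ontology):
        rec = PredictionRecord(
            "p", {"pvp": 0.92, "tail": 0.78}, frozenset({"pvp", "tail"}), False
        )
        assert top_confidence(rec, chain_ontology) == 0.92

    def test_unknown_is_zero(self, chain_ontology):
        rec = PredictionRecord("p", {"pvp": 0.2}, frozenset(), True)
        assert top_confidence(rec, chain_ontology) == 0.0

    def test_single_root(self, chain_ontology):
        rec = PredictionRecord("p", {"lysis": 0.6}, frozenset({"lysis"}), False)
        assert top_confidence(rec, chain_ontology) == 0.6


class TestCascadePersistence:
    def test_save_load_identical_predictions(self, trained_cascade, synth, tmp_path):
        from phannot.models import TrainedCascade
        trained_cascade.save(tmp_path / "bundle")
        back = TrainedCascade.load(tmp_path / "bundle")
        probe = EmbeddingMatrix(synth.embeddings.ids[:40], synth.embeddings.vectors[:40])
        a = trained_cascade.predict(probe)
        b = back.predict(probe)
        assert [(r.protein_id, r.assigned, r.unknown) for r in a] == [
            (r.protein_id, r.assigned, r.unknown) for r in b
        ]
        for ra, rb in zip(a, b):
            assert ra.evaluated == rb.evaluated

    def test_gated_children_not_evaluated(self, trained_cascade, synth):
        records = trained_cascade.predict(synth.embeddings)
        ont = trained_cascade.ontology
        for rec in records[:300]:
            for cat, conf in rec.evaluated.items():
                parent = ont.categories[cat].parent
                if parent is not None:
                    assert rec.evaluated[parent] >= 0.5

    def test_dimension_mismatch_rejected(self, trained_cascade):
        bad = EmbeddingMatrix(["x"], np.zeros((1, 7)))
        with pytest.raises(ValueError, match="dimension"):
            trained_cascade.predict(bad)
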