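import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phannot.datasets import build_dataset, class_weights, split_clusters
from phannot.io import ClusterMap, HitTable
from phannot.labeling import annotate
from phannot.ontology import Category, Ontology


def _random_clusters(rng, n_clusters, n_proteins):
    return ClusterMap({
        f"p{i}": f"c{rng.integers(n_clusters)}" for i in range(n_proteins)
    })


class TestSplitClusters:
    def test_eighty_twenty_arithmetic(self):
        clusters = ClusterMap({f"p{i}": f"c{i}" for i in range(10)})
        split = split_clusters(clusters, 0.8, seed=0)
        assert len(split.train_clusters()) == 8
        assert len(split.test_clusters()) == 2

    def test_same_seed_same_assignment(self):
        clusters = ClusterMap({f"p{i}": f"c{i % 17}" for i in range(60)})
        a = split_clusters(clusters, seed=7)
        b = split_clusters(clusters, seed=7)
        assert a.assignment == b.assignment
        assert a.assignment != split_clusters(clusters, seed=8).assignment

    def test_no_protein_on_both_sides(self):
        rng = np.random.default_rng(3)
        clusters = _random_clusters(rng, 200, 1000)
        split = split_clusters(clusters, seed=3)
        train_ids = {
            p for p, c in clusters.member_to_cluster.items()
            if split.side(c) == "train"
        }
        test_ids = set(clusters.member_to_cluster) - train_ids
        assert not train_ids & test_ids
        for pid, cid in clusters.member_to_cluster.items():
            assert (pid in train_ids) == (split.side(cid) == "train")

    def test_fraction_bounds(self):
        clusters = ClusterMap({"a": "c1", "b": "c2"})
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                split_clusters(clusters, bad, seed=0)

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(min_value=2, max_value=300),
           frac=st.floats(min_value=0.05, max_value=0.95),
           seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_realized_fraction_close_to_target(self, n, frac, seed):
        clusters = ClusterMap({f"p{i}": f"c{i}" for i in range(n)})
        split = split_clusters(clusters, frac, seed=seed)
        assert abs(len(split.train_clusters()) - frac * n) <= 2
        assert len(split.train_clusters()) >= 1 and len(split.test_clusters()) >= 1


@pytest.fixture
def toy_setup(toy_ontology):
    # 6 proteins, 3 clusters; c3 is conflicted for pvp (tail + endolysin)
    rows = [
        ("p1", "g1", "tail protein", 1e-9, 0.9),
        ("p2", "g1", "tail protein", 1e-9, 0.9),
        ("p3", "g2", "endolysin", 1e-9, 0.9),
        ("p4", "g3", "major capsid protein", 1e-9, 0.9),
        ("p5", "g4", "tail protein", 1e-9, 0.9),
        ("p6", "g2", "endolysin", 1e-9, 0.9),
    ]
    hits = HitTable(pd.DataFrame(
        rows, columns=["protein_id", "phrog_id", "annotation_term", "e_value", "coverage"]
    ))
    labels = annotate(hits, toy_ontology)
    clusters = ClusterMap({
        "p1": "c1", "p2": "c1", "p3": "c2", "p4": "c2", "p5": "c3", "p6": "c3",
    })
    split = split_clusters(clusters, 0.5, seed=0)
    return labels, clusters, split


class TestBuildDataset:
    def test_conflicted_cluster_fully_excluded(self, toy_ontology, toy_setup):
        labels, clusters, split = toy_setup
        # c3 holds p5 (tail -> pvp positive) and p6 (endolysin -> pvp negative)
        ds = build_dataset("pvp", labels, clusters, toy_ontology, split)
        assert {"p5", "p6"} <= ds.excluded
        assert not {"p5", "p6"} & (ds.positives | ds.negatives)

    def test_one_negative_per_cluster_for_root(self, toy_ontology, toy_setup):
        labels, clusters, split = toy_setup
        ds = build_dataset("lysis", labels, clusters, toy_ontology, split)
        # lysis negatives: p1, p2 (c1), p4 (c2 - p3 is positive, no conflict?
        # c2 holds p3 endolysin (positive) and p4 capsid (negative) -> conflicted
        assert ds.excluded >= {"p3", "p4"}
        by_cluster = {}
        for pid in ds.negatives:
            by_cluster.setdefault(clusters.cluster_of(pid), []).append(pid)
        assert all(len(v) == 1 for v in by_cluster.values())

    def test_parent_only_protein_excluded_from_child(self, toy_ontology):
        rows = [
            ("p1", "g1", "phage virion protein", 1e-9, 0.9),  # pvp only
            ("p2", "g2", "tail protein", 1e-9, 0.9),
            ("p3", "g3", "major capsid protein", 1e-9, 0.9),
        ]
        hits = HitTable(pd.DataFrame(
            rows, columns=["protein_id", "phrog_id", "annotation_term", "e_value", "coverage"]
        ))
        labels = annotate(hits, toy_ontology)
        clusters = ClusterMap({"p1": "c1", "p2": "c2", "p3": "c3"})
        split = split_clusters(clusters, 0.5, seed=0)
        ds = build_dataset("tail", labels, clusters, toy_ontology, split)
        assert "p1" in ds.excluded          # parent-only: too general
        assert "p2" in ds.positives
        assert "p3" in ds.negatives         # sibling-labeled: informative negative

    def test_unannotated_proteins_invisible(self, toy_ontology, toy_setup):
        labels, clusters, split = toy_setup
        clusters2 = ClusterMap(dict(clusters.member_to_cluster, p9="c1"))
        ds = build_dataset("pvp", labels, clusters2, toy_ontology, split)
        assert "p9" not in ds.positives | ds.negatives | ds.excluded

    def test_sets_are_disjoint(self, toy_ontology, toy_setup):
        labels, clusters, split = toy_setup
        for cat in ("pvp", "tail", "lysis", "lysin"):
            ds = build_dataset(cat, labels, clusters, toy_ontology, split)
            assert not ds.positives & ds.negatives
            assert not ds.excluded & (ds.positives | ds.negatives)

    def test_child_universe_within_parent_labels(self, toy_ontology, toy_setup):
        labels, clusters, split = toy_setup
        ds = build_dataset("tail", labels, clusters, toy_ontology, split)
        for pid in ds.positives | ds.negatives:
            assert "pvp" in labels.labels_of(pid)

    def test_nonviable_warning(self, toy_setup):
        labels, clusters, split = toy_setup
        ont = Ontology([Category("pvp", terms={"tail protein"}, min_train_clusters=50)])
        with pytest.warns(UserWarning, match="nonviable"):
            ds = build_dataset("pvp", labels, clusters, ont, split)
        assert not ds.viable


class TestClassWeights:
    def _ds(self, n_pos, n_neg):
        clusters = ClusterMap(
            {f"p{i}": f"c{i}" for i in range(n_pos + n_neg)}
        )
        split = split_clusters(clusters, 0.8, seed=0)
        from phannot.datasets import CategoryDataset
        return CategoryDataset(
            category="x",
            positives={f"p{i}" for i in range(n_pos)},
            negatives={f"p{i}" for i in range(n_pos, n_pos + n_neg)},
            excluded=set(),
            split=split,
            clusters=clusters,
        )

    def test_stated_examples(self):
        assert class_weights(self._ds(100, 300)) == {"positive": 4.0, "negative": 4 / 3}
        assert class_weights(self._ds(50, 50)) == {"positive": 2.0, "negative": 2.0}
        assert class_weights(self._ds(1, 999)) == {"positive": 1000.0, "negative": 1000 / 999}

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(self._ds(0, 5))

    @settings(max_examples=50, deadline=None)
    @given(n_pos=st.integers(min_value=1, max_value=500),
           n_neg=st.integers(min_value=1, max_value=500))
    def test_inverse_frequency_to_machine_precision(self, n_pos, n_neg):
        w = class_weights(self._ds(n_pos, n_neg))
        total = n_pos + n_neg
        assert w["positive"] == pytest.approx(1.0 / (n_pos / total), rel=1e-15)
        assert w["negative"] == pytest.approx(1.0 / (n_neg / total), rel=1e-15)
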