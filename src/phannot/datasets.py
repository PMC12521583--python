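"""Per-category training sets with cluster-level splitting.

The unit of train/test splitting is the homology cluster, never the
protein: every member of a cluster lands on the same side, so sequence
similarity detectable by clustering cannot leak between training and
testing.  Each category then gets its own positive/negative/excluded
partition of the annotated proteins:

* clusters with contradictory annotations for the category are dropped;
* for general (root) categories the negative class keeps only one protein
  per cluster, which diversifies negatives and keeps class sizes closer;
* for subcategories only parent-labeled proteins participate, proteins
  annotated only at the parent level are excluded (too general to place),
  and all remaining negatives are kept since the pool is already small;
* class imbalance is corrected with inverse-frequency class weights.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClusterMap
from .labeling import LabelMatrix, Role, category_role, cluster_label_conflicts
from .ontology import Ontology

__all__ = [
    "SplitAssignment",
    "CategoryDataset",
    "split_clusters",
    "build_dataset",
    "class_weights",
]


@dataclass
class SplitAssignment:
    """Cluster -> {train, test} assignment, deterministic per seed."""

    assignment: dict[str, str]
    seed: int
    train_fraction: float

    def side(self, cluster_id: str) -> str:
        return self.assignment[cluster_id]

    def train_clusters(self) -> set[str]:
        return {c for c, s in self.assignment.items() if s == "train"}

    def test_clusters(self) -> set[str]:
        return {c for c, s in self.assignment.items() if s == "test"}

    def content_hash(self) -> str:
        payload = "\n".join(f"{c}\t{s}" for c, s in sorted(self.assignment.items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CategoryDataset:
    """Positive/negative/excluded protein sets for one category model."""

    category: str
    positives: set[str]
    negatives: set[str]
    excluded: set[str]
    split: SplitAssignment
    clusters: ClusterMap
    viable: bool = True
    n_positive_clusters: int = 0
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positive and negative sets overlap")
        if self.excluded & (self.positives | self.negatives):
            raise ValueError("excluded set overlaps a training class")

    def _side_ids(self, ids: set[str], side: str) -> list[str]:
        return sorted(
            pid
            for pid in ids
            if self.split.side(self.clusters.cluster_of(pid)) == side
        )

    def train_positives(self) -> list[str]:
        return self._side_ids(self.positives, "train")

    def train_negatives(self) -> list[str]:
        return self._side_ids(self.negatives, "train")

    def test_positives(self) -> list[str]:
        return self._side_ids(self.positives, "test")

    def test_negatives(self) -> list[str]:
        return self._side_ids(self.negatives, "test")

    def manifest(self) -> pd.DataFrame:
        rows = []
        for role, ids in (
            ("pos", self.positives),
            ("neg", self.negatives),
            ("excluded", self.excluded),
        ):
            for pid in sorted(ids):
                cid = self.clusters.cluster_of(pid)
                rows.append(
                    {
                        "protein_id": pid,
                        "role": role,
                        "side": self.split.side(cid),
                        "cluster_id": cid,
                    }
                )
        return pd.DataFrame(rows, columns=["protein_id", "role", "side", "cluster_id"])


def split_clusters(
    clusters: ClusterMap, train_fraction: float = 0.8, seed: int = 0
) -> SplitAssignment:
    """Randomly assign whole clusters to the training or testing side.

    Deterministic for a fixed seed; the realized training fraction is
    ``round(train_fraction * n_clusters)`` clusters.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    ids = clusters.clusters()
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)  # both sides nonempty
    train = {ids[i] for i in order[:n_train]}
    assignment = {cid: ("train" if cid in train else "test") for cid in ids}
    return SplitAssignment(assignment, seed=seed, train_fraction=train_fraction)


def build_dataset(
    category: str,
    labels: LabelMatrix,
    clusters: ClusterMap,
    ont: Ontology,
    split: SplitAssignment,
) -> CategoryDataset:
    """Assemble one category's training universe.

    Applies, in order: (1) role classification of every annotated protein
    (candidate universe, overrides, parent restriction); (2) exclusion of
    conflicted clusters; (3) one-negative-per-cluster downsampling for
    root categories — the surviving negative is the cluster representative
    when it is an eligible negative, else the lexicographically smallest
    eligible member, so the choice is deterministic without an RNG.
    Unannotated proteins never enter either class.
    """
    ont._require(category)
    is_root = ont.categories[category].parent is None
    conflicted = cluster_label_conflicts(labels, clusters, category, ont)

    positives: set[str] = set()
    negatives: set[str] = set()
    excluded: set[str] = set()
    for pid in labels.annotated_ids():
        if pid not in clusters:
            raise KeyError(f"annotated protein {pid!r} missing from cluster map")
        role = category_role(pid, category, labels, ont)
        if role is Role.IGNORED:
            continue
        if clusters.cluster_of(pid) in conflicted:
            excluded.add(pid)
            continue
        if role is Role.POSITIVE:
            positives.add(pid)
        elif role is Role.NEGATIVE:
            negatives.add(pid)
        else:
            excluded.add(pid)

    if is_root:
        by_cluster: dict[str, list[str]] = {}
        for pid in negatives:
            by_cluster.setdefault(clusters.cluster_of(pid), []).append(pid)
        kept: set[str] = set()
        for cid, members in by_cluster.items():
            rep = clusters.representatives.get(cid)
            kept.add(rep if rep in members else min(members))
        excluded |= negatives - kept
        negatives = kept

    n_pos_clusters = len({clusters.cluster_of(pid) for pid in positives})
    floor = ont.categories[category].min_train_clusters
    viable = n_pos_clusters >= floor and bool(positives) and bool(negatives)
    if not viable:
        warnings.warn(
            f"category {category!r} nonviable: {n_pos_clusters} positive "
            f"cluster(s) (floor {floor}), {len(positives)} positives, "
            f"{len(negatives)} negatives",
            stacklevel=2,
        )

    ds = CategoryDataset(
        category=category,
        positives=positives,
        negatives=negatives,
        excluded=excluded,
        split=split,
        clusters=clusters,
        viable=viable,
        n_positive_clusters=n_pos_clusters,
    )
    if positives and negatives:
        ds.weights = class_weights(ds)
    return ds


def class_weights(ds: CategoryDataset) -> dict[str, float]:
    """Inverse-frequency class weights: w(c) = 1 / (|c| / (|pos| + |neg|))."""
    n_pos, n_neg = len(ds.positives), len(ds.negatives)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"category {ds.category!r}: empty training class")
    total = n_pos + n_neg
    return {"positive": 1.0 / (n_pos / total), "negative": 1.0 / (n_neg / total)}
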