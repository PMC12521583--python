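"""Holdout-homolog robustness protocol.

Cluster-level splitting removes leakage that sequence-sequence clustering
can see, but remote homologs may still straddle the split.  The stress
test here goes further: pick one homologous group (a profile-HMM family),
remove it and every similar group from training entirely, retrain the
category model, and score it on the held-out group's proteins.  A model
that still recovers the held-out proteins has learned a functional signal
beyond anything resembling its training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SplitAssignment, build_dataset
from .evaluation import precision_sensitivity_f1
from .io import ClusterMap, EmbeddingMatrix, HitTable, SimilarityGraph
from .labeling import LabelMatrix
from .ontology import Ontology

__all__ = ["HoldoutPlan", "HoldoutResult", "make_holdout", "run_holdout", "eligible_phrogs"]


@dataclass
class HoldoutPlan:
    """Training/testing protein sets for one holdout iteration."""

    category: str
    phrog_id: str
    removed_phrogs: frozenset[str]
    train_positives: list[str]
    train_negatives: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        train = set(self.train_positives) | set(self.train_negatives)
        if train & set(self.test_ids):
            raise ValueError("holdout train and test sets overlap")


@dataclass
class HoldoutResult:
    plan: HoldoutPlan
    precision: float  # NaN when no positive predictions (zero division)
    sensitivity: float
    f1: float


def eligible_phrogs(
    category: str,
    hits: HitTable,
    labels: LabelMatrix,
    ont: Ontology,
    min_proteins: int = 5,
) -> list[str]:
    """Homologous groups with >= ``min_proteins`` proteins labeled with the category."""
    ont._require(category)
    counts: dict[str, int] = {}
    for pid in hits.proteins():
        if category in labels.labels_of(pid):
            counts[hits.phrog_of(pid)] = counts.get(hits.phrog_of(pid), 0) + 1
    return sorted(p for p, n in counts.items() if n >= min_proteins)


def make_holdout(
    category: str,
    hits: HitTable,
    sim: SimilarityGraph,
    labels: LabelMatrix,
    clusters: ClusterMap,
    ont: Ontology,
    phrog_id: str,
    closure: str = "direct",
) -> HoldoutPlan:
    """Build one holdout plan around ``phrog_id``.

    ``removed_phrogs`` is the group itself plus its similarity neighbors
    (``closure="direct"``) or its whole similarity component
    (``closure="component"``).  The training set is the category's full
    dataset minus every protein whose best hit lands in a removed group;
    removed proteins are dropped, not converted to negatives.  The test
    set is the held-out group's proteins that carry category truth.
    """
    if closure not in ("direct", "component"):
        raise ValueError("closure must be 'direct' or 'component'")
    phrog_id = str(phrog_id)
    holdout_ids = [
        pid
        for pid in hits.proteins()
        if hits.phrog_of(pid) == phrog_id and category in labels.labels_of(pid)
    ]
    if not holdout_ids:
        raise ValueError(
            f"group {phrog_id!r} has no protein labeled with {category!r}"
        )
    if closure == "component":
        removed = frozenset(sim.component(phrog_id))
    else:
        removed = frozenset({phrog_id} | set(sim.neighbors(phrog_id)))

    # all-train split: holdout testing replaces the 80/20 test side
    all_train = SplitAssignment(
        {cid: "train" for cid in clusters.clusters()}, seed=0, train_fraction=1.0
    )
    ds = build_dataset(category, labels, clusters, ont, all_train)

    def keep(pid: str) -> bool:
        return pid not in hits or hits.phrog_of(pid) not in removed

    return HoldoutPlan(
        category=category,
        phrog_id=phrog_id,
        removed_phrogs=removed,
        train_positives=[p for p in sorted(ds.positives) if keep(p)],
        train_negatives=[p for p in sorted(ds.negatives) if keep(p)],
        test_ids=sorted(holdout_ids),
    )


def score_holdout(
    plan: HoldoutPlan,
    emb: EmbeddingMatrix,
    threshold: float = 0.5,
    random_state: int = 0,
    **hyperparameters,
) -> HoldoutResult:
    """Retrain on the plan's training set and score on the held-out proteins.

    Every held-out protein is a true positive by construction, so FP = 0
    and precision is either 1 or undefined (no positive predictions).
    """
    if not plan.train_positives or not plan.train_negatives:
        raise ValueError("holdout training set lost a whole class")
    ids = plan.train_positives + plan.train_negatives
    X = emb.matrix_for(ids)
    y = np.concatenate(
        [
            np.ones(len(plan.train_positives), dtype=int),
            np.zeros(len(plan.train_negatives), dtype=int),
        ]
    )
    total = len(ids)
    weight = {1: total / len(plan.train_positives), 0: total / len(plan.train_negatives)}
    from .models import CalibratedSVC

    est = CalibratedSVC(class_weight=weight, random_state=random_state, **hyperparameters)
    est.fit(X, y)
    conf = est.confidence(emb.matrix_for(plan.test_ids))
    tp = int((conf >= threshold).sum())
    fn = len(plan.test_ids) - tp
    precision, sensitivity, f1 = precision_sensitivity_f1(tp, 0, fn)
    return HoldoutResult(plan, precision, sensitivity, f1)


def run_holdout(
    category: str,
    hits: HitTable,
    sim: SimilarityGraph,
    labels: LabelMatrix,
    clusters: ClusterMap,
    ont: Ontology,
    emb: EmbeddingMatrix,
    n_iter: int = 10,
    seed: int = 0,
    closure: str = "direct",
    threshold: float = 0.5,
    min_proteins: int = 5,
    random_state: int | None = None,
) -> list[HoldoutResult]:
    """Sample ``n_iter`` distinct holdout groups, retrain and score each.

    Groups are sampled uniformly (seeded) from those with at least
    ``min_proteins`` category-labeled proteins; raises when fewer than
    ``n_iter`` are eligible.
    """
    pool = eligible_phrogs(category, hits, labels, ont, min_proteins=min_proteins)
    if len(pool) < n_iter:
        raise ValueError(
            f"category {category!r}: only {len(pool)} eligible group(s) "
            f"for {n_iter} iterations"
        )
    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=n_iter, replace=False)]
    results = []
    for phrog in chosen:
        plan = make_holdout(
            category, hits, sim, labels, clusters, ont, phrog, closure=closure
        )
        results.append(
            score_holdout(
                plan,
                emb,
                threshold=threshold,
                random_state=seed if random_state is None else random_state,
            )
        )
    return results
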