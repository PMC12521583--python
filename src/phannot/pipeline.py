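"""End-to-end workflow helpers: datasets for every category, cascade
training, and per-category scoring on the held-out cluster split."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import CategoryDataset, SplitAssignment, build_dataset
from .evaluation import confusion, precision_sensitivity_f1
from .io import ClusterMap, EmbeddingMatrix
from .labeling import LabelMatrix, Role, category_role
from .models import PredictionRecord, TrainedCascade, train_cascade
from .ontology import Ontology

__all__ = [
    "build_all_datasets",
    "fit_pipeline",
    "category_eval_ids",
    "score_cascade",
]


def build_all_datasets(
    labels: LabelMatrix,
    clusters: ClusterMap,
    ont: Ontology,
    split: SplitAssignment,
) -> dict[str, CategoryDataset]:
    """One dataset per ontology category (viability flagged, not filtered)."""
    return {
        cat.name: build_dataset(cat.name, labels, clusters, ont, split)
        for cat in ont
    }


def fit_pipeline(
    labels: LabelMatrix,
    clusters: ClusterMap,
    ont: Ontology,
    emb: EmbeddingMatrix,
    split: SplitAssignment,
    threshold: float = 0.5,
    random_state: int = 0,
    **hyperparameters,
) -> TrainedCascade:
    datasets = build_all_datasets(labels, clusters, ont, split)
    return train_cascade(
        datasets,
        emb,
        ont,
        threshold=threshold,
        random_state=random_state,
        **hyperparameters,
    )


def category_eval_ids(
    category: str,
    truth: LabelMatrix,
    clusters: ClusterMap,
    split: SplitAssignment,
    ont: Ontology,
    side: str = "test",
) -> list[str]:
    """Evaluable proteins for one category on one side of the split.

    The evaluation universe mirrors the category's training-set
    definition applied to the truth labels: annotated proteins for a root
    category, parent-labeled proteins carrying subcategory information
    for a child (parent-only annotations are too general to validate a
    child prediction against).  Unlike training, negatives are NOT
    downsampled to one per cluster — metrics cover the whole test side.
    """
    out = []
    for pid in sorted(truth.labels):
        if pid not in clusters or split.side(clusters.cluster_of(pid)) != side:
            continue
        if category_role(pid, category, truth, ont) in (Role.POSITIVE, Role.NEGATIVE):
            out.append(pid)
    return out


def score_cascade(
    cascade: TrainedCascade,
    emb: EmbeddingMatrix,
    truth: LabelMatrix,
    clusters: ClusterMap,
    split: SplitAssignment,
    threshold: float = 0.5,
    side: str = "test",
) -> pd.DataFrame:
    """Per-category precision/sensitivity/F1 on one side of the split."""
    ont = cascade.ontology
    all_ids = sorted(
        pid
        for pid in truth.labels
        if pid in clusters and split.side(clusters.cluster_of(pid)) == side
    )
    records = cascade.predict(emb.subset(all_ids), threshold=threshold)
    by_id: dict[str, PredictionRecord] = {r.protein_id: r for r in records}
    rows = []
    for category in cascade.categories():
        ids = category_eval_ids(category, truth, clusters, split, ont, side=side)
        preds = [by_id[p] for p in ids]
        if not preds:
            rows.append(
                {
                    "category": category,
                    "n": 0,
                    "tp": 0,
                    "fp": 0,
                    "fn": 0,
                    "tn": 0,
                    "precision": np.nan,
                    "sensitivity": np.nan,
                    "f1": np.nan,
                }
            )
            continue
        tp, fp, fn, tn = confusion(preds, truth, category, ont, threshold)
        precision, sensitivity, f1 = precision_sensitivity_f1(tp, fp, fn)
        rows.append(
            {
                "category": category,
                "n": len(ids),
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "tn": tn,
                "precision": precision,
                "sensitivity": sensitivity,
                "f1": f1,
            }
        )
    return pd.DataFrame(rows)
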