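"""Threshold-dependent metrics and per-cluster prediction consistency.

Precision, sensitivity (recall) and F1 are reported per category as
functions of the confidence threshold.  Precision is *undefined* — not
zero — at thresholds where the model assigns nothing, and undefined values
are excluded from averages.  Consistency audits ask whether homologous
proteins (clustermates) receive coherent predictions, binned as: identical
assignments, identical up to unknowns, overlapping general functions, or
outright disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ClusterMap
from .labeling import LabelMatrix
from .models import PredictionRecord
from .ontology import Ontology

__all__ = [
    "EvalCurve",
    "ConsistencyReport",
    "confusion",
    "confusion_clusters",
    "metric_curve",
    "precision_sensitivity_f1",
    "cluster_consistency",
]

CONSISTENCY_BINS = (
    "identical",
    "identical_with_unknowns",
    "partial_overlap",
    "differing",
)


@dataclass
class EvalCurve:
    """Per-threshold metrics for one category (NaN = undefined)."""

    category: str
    thresholds: np.ndarray
    precision: np.ndarray
    sensitivity: np.ndarray
    f1: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.category,
                "threshold": self.thresholds,
                "precision": self.precision,
                "sensitivity": self.sensitivity,
                "f1": self.f1,
            }
        )


@dataclass
class ConsistencyReport:
    """Cluster counts per agreement bin (clusters of size >= 2 only)."""

    counts: dict[str, int]
    all_unknown: int
    total: int

    def fractions(self) -> dict[str, float]:
        if self.total == 0:
            return {b: float("nan") for b in self.counts}
        return {b: c / self.total for b, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        fr = self.fractions()
        rows = [
            {"bin": b, "count": self.counts[b], "fraction": fr[b]}
            for b in CONSISTENCY_BINS
        ]
        rows.append(
            {
                "bin": "all_unknown",
                "count": self.all_unknown,
                "fraction": float("nan"),
            }
        )
        return pd.DataFrame(rows, columns=["bin", "count", "fraction"])


def _assigned_set_at(rec: PredictionRecord, ont: Ontology, t: float) -> set[str]:
    """Re-threshold a record's evaluated confidences.

    Assignment at threshold ``t`` requires a category and its evaluated
    ancestors to clear ``t``; categories never evaluated (gated off)
    cannot be assigned.  Lets one prediction pass be scored over a whole
    threshold grid.
    """
    out: set[str] = set()
    for cat in sorted(rec.evaluated, key=lambda c: (ont.depth(c), c)):
        if rec.evaluated[cat] < t:
            continue
        parent = ont.categories[cat].parent
        if parent is None or parent in out:
            out.add(cat)
    return out


def confusion(
    preds: list[PredictionRecord],
    truth: LabelMatrix,
    category: str,
    ont: Ontology,
    t: float = 0.5,
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) for one category at threshold ``t``.

    The id space is the given records; assignment re-applies the gating
    rule on the stored confidences so the same records can be scored over
    a whole threshold grid.
    """
    if not preds:
        raise ValueError("empty evaluable set")
    tp = fp = fn = tn = 0
    for rec in preds:
        assigned = category in _assigned_set_at(rec, ont, t)
        labeled = category in truth.labels_of(rec.protein_id)
        if assigned and labeled:
            tp += 1
        elif assigned:
            fp += 1
        elif labeled:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def confusion_clusters(
    preds: list[PredictionRecord],
    truth: LabelMatrix,
    category: str,
    ont: Ontology,
    clusters: ClusterMap,
    t: float = 0.5,
) -> tuple[int, int, int, int]:
    """Cluster-level (TP, FP, FN, TN): one vote per homology cluster.

    A cluster counts as labeled when any member carries the category in
    truth, and as assigned when any member is assigned the category at
    ``t`` — the coarser granularity used when reporting annotated-cluster
    counts rather than per-protein metrics.
    """
    if not preds:
        raise ValueError("empty evaluable set")
    by_cluster: dict[str, list[PredictionRecord]] = {}
    for rec in preds:
        by_cluster.setdefault(clusters.cluster_of(rec.protein_id), []).append(rec)
    tp = fp = fn = tn = 0
    for members in by_cluster.values():
        assigned = any(
            category in _assigned_set_at(rec, ont, t) for rec in members
        )
        labeled = any(
            category in truth.labels_of(rec.protein_id) for rec in members
        )
        if assigned and labeled:
            tp += 1
        elif assigned:
            fp += 1
        elif labeled:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def precision_sensitivity_f1(
    tp: int, fp: int, fn: int
) -> tuple[float, float, float]:
    """Metrics from counts; NaN where a denominator is zero."""
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return precision, sensitivity, f1


def metric_curve(
    preds: list[PredictionRecord],
    truth: LabelMatrix,
    category: str,
    ont: Ontology,
    grid=None,
) -> EvalCurve:
    """Precision/sensitivity/F1 as functions of the confidence threshold."""
    if grid is None:
        grid = np.arange(0.05, 1.0, 0.05)
    grid = np.asarray(grid, dtype=float)
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly ascending")
    p = np.empty(grid.size)
    s = np.empty(grid.size)
    f = np.empty(grid.size)
    for i, t in enumerate(grid):
        tp, fp, fn, _ = confusion(preds, truth, category, ont, t)
        p[i], s[i], f[i] = precision_sensitivity_f1(tp, fp, fn)
    return EvalCurve(category, grid, p, s, f)


def cluster_consistency(
    preds: list[PredictionRecord],
    clusters: ClusterMap,
    ont: Ontology,
) -> ConsistencyReport:
    """Audit agreement of predictions within homology clusters.

    Clusters of size >= 2 are binned:

    * ``identical`` — all members share the same nonempty assignment;
    * ``identical_with_unknowns`` — all nonempty assignments agree but
      >= 1 member is unknown;
    * ``partial_overlap`` — >= 2 distinct nonempty assignments whose
      root-category (general-function) sets intersect;
    * ``differing`` — >= 2 distinct nonempty assignments with disjoint
      root sets.

    All-unknown clusters are counted separately; singletons are skipped.
    """
    by_cluster: dict[str, list[PredictionRecord]] = {}
    for rec in preds:
        if rec.protein_id not in clusters:
            raise KeyError(f"predicted protein {rec.protein_id!r} has no cluster")
        by_cluster.setdefault(clusters.cluster_of(rec.protein_id), []).append(rec)

    counts = {b: 0 for b in CONSISTENCY_BINS}
    all_unknown = 0
    total = 0
    for members in by_cluster.values():
        if len(members) < 2:
            continue
        nonempty = [rec.assigned for rec in members if not rec.unknown]
        n_unknown = len(members) - len(nonempty)
        if not nonempty:
            all_unknown += 1
            continue
        total += 1
        distinct = set(nonempty)
        if len(distinct) == 1:
            counts["identical" if n_unknown == 0 else "identical_with_unknowns"] += 1
            continue
        roots = [
            frozenset(c for c in a if ont.categories[c].parent is None)
            for a in distinct
        ]
        overlap = all(r1 & r2 for i, r1 in enumerate(roots) for r2 in roots[i + 1:])
        counts["partial_overlap" if overlap else "differing"] += 1
    return ConsistencyReport(counts, all_unknown, total)
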