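"""From profile-HMM best hits to multi-label category assignments.

A protein's label set is whatever its best-hit annotation term maps to in
the ontology, closed under ancestry.  Proteins whose best hit points to an
unknown-function group keep an empty label set but retain the group id,
because that id still matters for annotation-status bookkeeping: such a
protein may be "rescued" when its group shows strong profile-profile
similarity to an annotated group, or when an annotated protein sits in the
same homology cluster.  Rescue is reporting only — rescued proteins never
enter training classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .io import ClusterMap, HitTable, SimilarityGraph, UNKNOWN_TERM
from .ontology import Ontology, normalize_term

__all__ = [
    "LabelMatrix",
    "Status",
    "AnnotationStatus",
    "Role",
    "annotate",
    "annotation_status",
    "category_role",
    "cluster_label_conflicts",
]


class LabelMatrix:
    """Per-protein category label sets plus the source annotation term."""

    def __init__(
        self,
        labels: dict[str, frozenset[str]],
        source_term: dict[str, str] | None = None,
        best_phrog: dict[str, str] | None = None,
    ) -> None:
        self.labels = {pid: frozenset(cats) for pid, cats in labels.items()}
        self.source_term = dict(source_term or {})
        self.best_phrog = dict(best_phrog or {})

    def labels_of(self, pid: str) -> frozenset[str]:
        return self.labels.get(pid, frozenset())

    def annotated_ids(self) -> list[str]:
        """Proteins carrying at least one category label."""
        return sorted(pid for pid, cats in self.labels.items() if cats)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, pid: str) -> bool:
        return pid in self.labels


class Status(str, Enum):
    """Annotation status of one protein."""

    DIRECT = "direct"
    RESCUED_BY_SIMILAR_PHROG = "rescued_by_similar_phrog"
    RESCUED_BY_CLUSTER = "rescued_by_cluster"
    FULLY_UNANNOTATED = "fully_unannotated"


@dataclass
class AnnotationStatus:
    protein_status: dict[str, Status]
    cluster_unannotated: dict[str, bool]  # cluster_id -> fully unannotated?

    def counts(self) -> dict[str, int]:
        out = {s.value: 0 for s in Status}
        for status in self.protein_status.values():
            out[status.value] += 1
        return out

    def to_frame(self, labels: LabelMatrix) -> pd.DataFrame:
        rows = [
            {
                "protein_id": pid,
                "status": status.value,
                "best_phrog": labels.best_phrog.get(pid, ""),
                "labels": ";".join(sorted(labels.labels_of(pid))),
            }
            for pid, status in sorted(self.protein_status.items())
        ]
        return pd.DataFrame(rows, columns=["protein_id", "status", "best_phrog", "labels"])


def annotate(hits: HitTable, ont: Ontology) -> LabelMatrix:
    """Label every hit protein with the categories its best-hit term maps to.

    Unknown-function hits yield empty label sets; the group id is kept for
    downstream status analysis.
    """
    labels: dict[str, frozenset[str]] = {}
    terms: dict[str, str] = {}
    phrogs: dict[str, str] = {}
    for row in hits.frame.itertuples(index=False):
        term = normalize_term(str(row.annotation_term))
        cats = frozenset() if term == UNKNOWN_TERM else frozenset(ont.map_term(term))
        labels[row.protein_id] = cats
        terms[row.protein_id] = term
        phrogs[row.protein_id] = str(row.phrog_id)
    return LabelMatrix(labels, terms, phrogs)


def _annotated_phrogs(labels: LabelMatrix) -> set[str]:
    return {
        phrog
        for pid, phrog in labels.best_phrog.items()
        if labels.labels_of(pid)
    }


def annotation_status(
    labels: LabelMatrix,
    hits: HitTable,
    clusters: ClusterMap,
    sim: SimilarityGraph,
    ont: Ontology,
    sim_evalue: float = 0.001,
    sim_coverage: float = 0.80,
) -> AnnotationStatus:
    """Classify every clustered protein by how (if at all) it is annotated.

    * ``direct`` — best hit to an annotated group;
    * ``rescued_by_similar_phrog`` — best hit to an unknown-function group
      that has a similarity edge (e-value < ``sim_evalue`` AND coverage
      strictly > ``sim_coverage``) to an annotated group;
    * ``rescued_by_cluster`` — no such hit, but an annotated protein
      shares the homology cluster;
    * ``fully_unannotated`` — none of the above.

    When both rescue rules apply, the similar-group rescue wins: it is a
    property of the protein itself rather than of its clustermates.  A
    cluster is fully unannotated iff all of its members are.
    """
    for pid in labels.labels:
        if pid not in clusters:
            raise KeyError(f"labeled protein {pid!r} missing from cluster map")

    annotated_phrogs = _annotated_phrogs(labels)
    status: dict[str, Status] = {}
    for cid in clusters.clusters():
        members = clusters.members(cid)
        direct = {pid for pid in members if labels.labels_of(pid)}
        for pid in members:
            if pid in direct:
                status[pid] = Status.DIRECT
                continue
            phrog = labels.best_phrog.get(pid)
            rescued_sim = False
            if phrog is not None:
                for nb, (ev, cov) in sim.neighbors(phrog).items():
                    if nb in annotated_phrogs and ev < sim_evalue and cov > sim_coverage:
                        rescued_sim = True
                        break
            if rescued_sim:
                status[pid] = Status.RESCUED_BY_SIMILAR_PHROG
            elif direct:
                status[pid] = Status.RESCUED_BY_CLUSTER
            else:
                status[pid] = Status.FULLY_UNANNOTATED
    cluster_unannotated = {
        cid: all(
            status[pid] is Status.FULLY_UNANNOTATED for pid in clusters.members(cid)
        )
        for cid in clusters.clusters()
    }
    return AnnotationStatus(status, cluster_unannotated)


class Role(str, Enum):
    """Role a protein plays in one category's training universe."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    EXCLUDED = "excluded"
    IGNORED = "ignored"  # outside the candidate universe (or unannotated)


def category_role(
    pid: str, category: str, labels: LabelMatrix, ont: Ontology
) -> Role:
    """Classify one protein for one category's training set, pre-filtering.

    Rules, in order:

    1. unannotated proteins are invisible to training;
    2. a per-term override for this category wins (``force_positive`` /
       ``force_negative`` / ``exclude``), subject to the parent-universe
       restriction for subcategories;
    3. for a root category every annotated protein is a candidate:
       positive iff labeled with the category, else negative;
    4. for a subcategory only parent-labeled proteins are candidates:
       positive iff labeled with the category; excluded when the labels
       carry no subcategory information below the parent (annotation too
       general to resolve); otherwise negative.

    Per-cluster conflict exclusion and one-negative-per-cluster
    downsampling happen later, at dataset-assembly time.
    """
    ont._require(category)
    cats = labels.labels_of(pid)
    if not cats:
        return Role.IGNORED
    parent = ont.categories[category].parent
    if parent is not None and parent not in cats:
        return Role.IGNORED
    directive = ont.overrides_for(category).get(labels.source_term.get(pid, ""))
    if directive == "exclude":
        return Role.EXCLUDED
    if directive == "force_positive":
        return Role.POSITIVE
    if directive == "force_negative":
        return Role.NEGATIVE
    if category in cats:
        return Role.POSITIVE
    if parent is not None:
        siblings_subtree = _descendants(parent, ont)
        if not (cats & siblings_subtree):
            return Role.EXCLUDED  # parent-only annotation, too general
    return Role.NEGATIVE


def _descendants(category: str, ont: Ontology) -> set[str]:
    out: set[str] = set()
    stack = list(ont.children(category))
    while stack:
        node = stack.pop()
        out.add(node)
        stack.extend(ont.children(node))
    return out


def cluster_label_conflicts(
    labels: LabelMatrix, clusters: ClusterMap, category: str, ont: Ontology
) -> set[str]:
    """Clusters holding contradictory annotations for one category.

    A cluster is conflicted iff it contains at least one protein whose
    annotations place it in the category's positive definition and one
    whose annotations place it in the negative definition.  Unannotated
    and excluded members are ignored.  Conflicted clusters are dropped
    from both classes so label noise inside homologous families cannot
    reach the classifier.
    """
    ont._require(category)
    conflicted: set[str] = set()
    for cid in clusters.clusters():
        roles = {
            category_role(pid, category, labels, ont)
            for pid in clusters.members(cid)
        }
        if Role.POSITIVE in roles and Role.NEGATIVE in roles:
            conflicted.add(cid)
    return conflicted
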