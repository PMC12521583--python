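"""Independent brute-force re-implementations of the dataset, status,
consistency and holdout rules, plus a random small-fixture generator.

These deliberately avoid the package's own code paths (beyond shared data
containers) so they can serve as oracles: every rule is written as a
direct, unoptimized transcription of its definition.
"""

from __future__ import annotations

import numpy as np

from phannot.io import ClusterMap, HitTable, SimilarityGraph, UNKNOWN_TERM
from phannot.labeling import LabelMatrix
from phannot.ontology import Category, Ontology

import pandas as pd


# ---------------------------------------------------------------------------
# random small fixtures


def random_fixture(seed: int):
    """A random ontology + <=30 proteins with labels, clusters, hits, edges."""
    rng = np.random.default_rng(seed)
    n_roots = int(rng.integers(1, 4))
    cats = []
    for r in range(n_roots):
        root = f"r{r}"
        cats.append(Category(root, terms={f"term {root}"}, min_train_clusters=0))
        for c in range(int(rng.integers(0, 3))):
            name = f"r{r}c{c}"
            cats.append(Category(name, parent=root, terms={f"term {name}"}, min_train_clusters=0))
    ont = Ontology(cats)
    terms = [f"term {c.name}" for c in ont] + [UNKNOWN_TERM]

    n_proteins = int(rng.integers(5, 31))
    n_phrogs = int(rng.integers(2, max(3, n_proteins // 2)))
    n_clusters = int(rng.integers(2, max(3, n_proteins // 2)))
    phrog_term = {f"g{i}": terms[int(rng.integers(len(terms)))] for i in range(n_phrogs)}

    rows = []
    member_to_cluster = {}
    for i in range(n_proteins):
        pid = f"p{i:02d}"
        member_to_cluster[pid] = f"c{int(rng.integers(n_clusters))}"
        if rng.random() < 0.85:  # some proteins have no hit at all
            phrog = f"g{int(rng.integers(n_phrogs))}"
            rows.append(
                {
                    "protein_id": pid,
                    "phrog_id": phrog,
                    "annotation_term": phrog_term[phrog],
                    "e_value": float(10.0 ** rng.uniform(-20, -4)),
                    "coverage": float(rng.uniform(0.5, 1.0)),
                }
            )
    clusters = ClusterMap(member_to_cluster)
    hits = HitTable(pd.DataFrame(rows, columns=["protein_id", "phrog_id", "annotation_term", "e_value", "coverage"]))

    labels = {}
    source = {}
    best = {}
    for row in rows:
        term = row["annotation_term"]
        labels[row["protein_id"]] = (
            frozenset() if term == UNKNOWN_TERM else frozenset(ont.map_term(term))
        )
        source[row["protein_id"]] = term
        best[row["protein_id"]] = row["phrog_id"]
    label_matrix = LabelMatrix(labels, source, best)

    edges = []
    phrog_ids = sorted(phrog_term)
    for i, a in enumerate(phrog_ids):
        for b in phrog_ids[i + 1:]:
            if rng.random() < 0.3:
                edges.append(
                    (a, b, float(10.0 ** rng.uniform(-10, -1)), float(rng.uniform(0.5, 1.0)))
                )
    sim = SimilarityGraph(edges)
    return ont, label_matrix, hits, clusters, sim


# ---------------------------------------------------------------------------
# rule oracles (straight transcriptions of the definitions)


def oracle_role(pid, category, labels: LabelMatrix, ont: Ontology) -> str:
    cats = labels.labels_of(pid)
    if not cats:
        return "ignored"
    parent = ont.categories[category].parent
    if parent is not None and parent not in cats:
        return "ignored"
    ov = ont.overrides_for(category).get(labels.source_term.get(pid, ""))
    if ov == "exclude":
        return "excluded"
    if ov == "force_positive":
        return "positive"
    if ov == "force_negative":
        return "negative"
    if category in cats:
        return "positive"
    if parent is not None:
        subtree = set()
        frontier = [parent]
        while frontier:
            node = frontier.pop()
            for child in ont.children(node):
                subtree.add(child)
                frontier.append(child)
        if not (cats & subtree):
            return "excluded"
    return "negative"


def oracle_build_dataset(category, labels, clusters, ont):
    """(positives, negatives, excluded) by literal rule application."""
    conflicted = set()
    for cid in clusters.clusters():
        roles = [oracle_role(p, category, labels, ont) for p in clusters.members(cid)]
        if "positive" in roles and "negative" in roles:
            conflicted.add(cid)
    pos, neg, exc = set(), set(), set()
    for pid in labels.labels:
        if not labels.labels_of(pid):
            continue
        role = oracle_role(pid, category, labels, ont)
        if role == "ignored":
            continue
        if clusters.cluster_of(pid) in conflicted:
            exc.add(pid)
        elif role == "positive":
            pos.add(pid)
        elif role == "negative":
            neg.add(pid)
        else:
            exc.add(pid)
    if ont.categories[category].parent is None:
        keep = set()
        for cid in {clusters.cluster_of(p) for p in neg}:
            members = sorted(p for p in neg if clusters.cluster_of(p) == cid)
            rep = clusters.representatives.get(cid)
            keep.add(rep if rep in members else members[0])
        exc |= neg - keep
        neg = keep
    return pos, neg, exc


def oracle_status(labels, hits, clusters, sim, ont, sim_evalue=0.001, sim_coverage=0.80):
    annotated_phrogs = {
        labels.best_phrog[p] for p in labels.labels if labels.labels_of(p)
        and p in labels.best_phrog
    }
    out = {}
    for cid in clusters.clusters():
        members = clusters.members(cid)
        has_direct = any(labels.labels_of(p) for p in members)
        for pid in members:
            if labels.labels_of(pid):
                out[pid] = "direct"
                continue
            phrog = labels.best_phrog.get(pid)
            rescued = False
            if phrog is not None:
                for nb, (ev, cov) in sim.neighbors(phrog).items():
                    if nb in annotated_phrogs and ev < sim_evalue and cov > sim_coverage:
                        rescued = True
            if rescued:
                out[pid] = "rescued_by_similar_phrog"
            elif has_direct:
                out[pid] = "rescued_by_cluster"
            else:
                out[pid] = "fully_unannotated"
    return out


def oracle_consistency(assigned_sets, clusters, ont):
    """bin counts from protein_id -> frozenset assignment (empty = unknown)."""
    by_cluster = {}
    for pid, assigned in assigned_sets.items():
        by_cluster.setdefault(clusters.cluster_of(pid), []).append(assigned)
    counts = {
        "identical": 0,
        "identical_with_unknowns": 0,
        "partial_overlap": 0,
        "differing": 0,
    }
    all_unknown = 0
    for members in by_cluster.values():
        if len(members) < 2:
            continue
        nonempty = [a for a in members if a]
        if not nonempty:
            all_unknown += 1
            continue
        distinct = set(nonempty)
        if len(distinct) == 1:
            if len(nonempty) == len(members):
                counts["identical"] += 1
            else:
                counts["identical_with_unknowns"] += 1
            continue
        roots = [
            frozenset(c for c in a if ont.categories[c].parent is None)
            for a in distinct
        ]
        pairwise = [
            bool(roots[i] & roots[j])
            for i in range(len(roots))
            for j in range(i + 1, len(roots))
        ]
        if all(pairwise):
            counts["partial_overlap"] += 1
        else:
            counts["differing"] += 1
    return counts, all_unknown


def oracle_removed_phrogs(sim: SimilarityGraph, phrog, closure="direct"):
    if closure == "direct":
        return {phrog} | set(sim.neighbors(phrog))
    seen = {phrog}
    frontier = [phrog]
    while frontier:
        node = frontier.pop()
        for nb in sim.neighbors(node):
            if nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    return seen
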