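"""Desk-scale synthetic benchmark with hierarchical embedding structure.

Emulates the geometry the real pipeline relies on: proteins of one
functional category occupy a region of embedding space, subcategories sit
inside their parent's region, and homologous groups (profile-HMM families)
form tight subclusters within a category.  Concretely, root-category
centers are placed ``delta`` apart, each child center is offset from its
parent by ``sigma_c``, each group center by a fraction of ``sigma_c`` from
its category center, and proteins scatter around their group center with
radius ``sigma_w``; ``delta > sigma_c > sigma_w`` makes categories
Bayes-separable by construction.  On top of the clean geometry the
generator adds the annotation pathologies the pipeline must tolerate:
unknown-function groups, label noise, an unannotated background far from
every category, and (optionally) clusters with deliberately contradictory
labels.

What it does not emulate: real protein-language-model embedding geometry
(anisotropy, shared substructure between related functions) or sequence
evolution; passing here shows the machinery is correct, not that any
accuracy carries over to real embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ClusterMap,
    EmbeddingMatrix,
    HitTable,
    SimilarityGraph,
    UNKNOWN_TERM,
)
from .labeling import LabelMatrix
from .ontology import Category, Ontology

__all__ = ["SynthConfig", "SynthDataset", "generate", "bayes_reference"]

DEFAULT_TREE = {
    "pvp": ["tail", "capsid"],
    "lysis": ["lysin", "holin"],
    "DNA-associated": ["nuclease", "integration"],
}


@dataclass
class SynthConfig:
    """Generator parameters; defaults define the standard benchmark.

    Distances are Euclidean in embedding space: ``delta`` separates root
    centers, ``sigma_c`` is the child-center offset from its parent,
    ``sigma_w`` the protein scatter radius around a group center.
    """

    dim: int = 64
    tree: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_TREE.items()}
    )
    n_phrogs_per_leaf: int = 10
    n_parent_only_phrogs: int = 2
    n_background_phrogs: int = 4
    proteins_per_phrog: tuple[int, int] = (15, 25)
    sigma_w: float = 0.15
    sigma_c: float = 1.5
    delta: float = 6.0
    phrog_offset: float = 0.3
    unannotated_fraction: float = 0.10
    label_noise_rate: float = 0.02
    similarity_edge_prob: float = 0.5
    n_conflict_clusters: int = 0
    min_train_clusters: int = 2
    seed: int = 0
    force_degenerate: bool = False

    def validate(self) -> None:
        if not self.force_degenerate and not (
            self.delta > self.sigma_c > self.sigma_w > 0
        ):
            raise ValueError("need delta > sigma_c > sigma_w > 0")
        for name, frac in (
            ("unannotated_fraction", self.unannotated_fraction),
            ("label_noise_rate", self.label_noise_rate),
            ("similarity_edge_prob", self.similarity_edge_prob),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.tree) + 1 > self.dim:
            raise ValueError(
                f"cannot place {len(self.tree)} separated root centers plus "
                f"background in {self.dim} dimensions"
            )
        lo, hi = self.proteins_per_phrog
        if not 1 <= lo <= hi:
            raise ValueError("proteins_per_phrog range invalid")


@dataclass
class SynthDataset:
    """A complete synthetic study: embeddings, truth, observations, graphs."""

    config: SynthConfig
    ontology: Ontology
    embeddings: EmbeddingMatrix
    labels_true: LabelMatrix
    labels_observed: LabelMatrix
    clusters: ClusterMap
    hits: HitTable
    similarity: SimilarityGraph
    category_centers: dict[str, np.ndarray]
    phrog_centers: dict[str, np.ndarray]
    phrog_category: dict[str, str | None]  # leaf/root category or None (background)
    background_center: np.ndarray


def _unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def _make_ontology(cfg: SynthConfig) -> Ontology:
    cats = []
    for root, children in cfg.tree.items():
        cats.append(
            Category(
                root,
                parent=None,
                terms={f"{root} general protein"},
                min_train_clusters=cfg.min_train_clusters,
            )
        )
        for child in children:
            cats.append(
                Category(
                    child,
                    parent=root,
                    terms={f"{child} protein"},
                    min_train_clusters=cfg.min_train_clusters,
                )
            )
    return Ontology(cats)


def generate(cfg: SynthConfig | None = None, seed: int | None = None) -> SynthDataset:
    """Generate a full synthetic dataset; deterministic per seed."""
    cfg = cfg or SynthConfig()
    if seed is not None:
        cfg = dataclass_replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ont = _make_ontology(cfg)

    category_centers: dict[str, np.ndarray] = {}
    for i, (root, children) in enumerate(cfg.tree.items()):
        center = np.zeros(cfg.dim)
        center[i] = cfg.delta
        category_centers[root] = center
        for child in children:
            category_centers[child] = center + cfg.sigma_c * _unit(rng, cfg.dim)
    background_center = np.zeros(cfg.dim)

    # groups: (phrog_id, category or None, annotation term)
    phrog_centers: dict[str, np.ndarray] = {}
    phrog_category: dict[str, str | None] = {}
    phrog_term: dict[str, str] = {}
    counter = 0

    def add_phrog(center: np.ndarray, category: str | None, term: str) -> str:
        nonlocal counter
        pid = f"phrog_{counter}"
        counter += 1
        phrog_centers[pid] = center + cfg.phrog_offset * _unit(rng, cfg.dim)
        phrog_category[pid] = category
        phrog_term[pid] = term
        return pid

    for root, children in cfg.tree.items():
        for _ in range(cfg.n_parent_only_phrogs):
            add_phrog(category_centers[root], root, f"{root} general protein")
        for child in children:
            for _ in range(cfg.n_phrogs_per_leaf):
                term = f"{child} protein"
                if rng.random() < cfg.unannotated_fraction:
                    term = UNKNOWN_TERM
                add_phrog(category_centers[child], child, term)
    for _ in range(cfg.n_background_phrogs):
        add_phrog(background_center, None, UNKNOWN_TERM)

    # proteins
    leaf_terms = [
        f"{child} protein" for children in cfg.tree.values() for child in children
    ]
    protein_ids: list[str] = []
    vectors: list[np.ndarray] = []
    true_labels: dict[str, frozenset[str]] = {}
    obs_terms: dict[str, str] = {}
    member_to_cluster: dict[str, str] = {}
    representatives: dict[str, str] = {}
    hit_rows: list[dict] = []
    p_counter = 0
    for phrog, center in phrog_centers.items():
        n = int(rng.integers(cfg.proteins_per_phrog[0], cfg.proteins_per_phrog[1] + 1))
        cluster_id = f"C_{phrog}"
        for j in range(n):
            pid = f"P{p_counter:05d}"
            p_counter += 1
            protein_ids.append(pid)
            vectors.append(
                center + rng.standard_normal(cfg.dim) * (cfg.sigma_w / np.sqrt(cfg.dim))
            )
            cat = phrog_category[phrog]
            if cat is None:
                true_labels[pid] = frozenset()
            else:
                true_labels[pid] = frozenset({cat} | set(ont.ancestors(cat)))
            term = phrog_term[phrog]
            if term not in (UNKNOWN_TERM,) and rng.random() < cfg.label_noise_rate:
                others = [t for t in leaf_terms if t != term]
                term = others[int(rng.integers(len(others)))]
            obs_terms[pid] = term
            member_to_cluster[pid] = cluster_id
            if j == 0:
                representatives[cluster_id] = pid
            hit_rows.append(
                {
                    "protein_id": pid,
                    "phrog_id": phrog,
                    "annotation_term": term,
                    "e_value": float(10.0 ** rng.uniform(-30, -4)),
                    "coverage": float(rng.uniform(0.85, 1.0)),
                }
            )

    # optional deliberately conflicted clusters: merge pairs of clusters
    # from different roots into one
    if cfg.n_conflict_clusters > 0:
        annotated = [
            p
            for p in phrog_centers
            if phrog_category[p] is not None and phrog_term[p] != UNKNOWN_TERM
        ]
        root_of = {
            p: (
                phrog_category[p]
                if ont.categories[phrog_category[p]].parent is None
                else ont.categories[phrog_category[p]].parent
            )
            for p in annotated
        }
        pairs = 0
        order = list(rng.permutation(annotated))
        while pairs < cfg.n_conflict_clusters and len(order) >= 2:
            a = order.pop()
            partner = next((b for b in order if root_of[b] != root_of[a]), None)
            if partner is None:
                break
            order.remove(partner)
            merged = f"C_{a}"
            for pid, cid in list(member_to_cluster.items()):
                if cid == f"C_{partner}":
                    member_to_cluster[pid] = merged
            representatives.pop(f"C_{partner}", None)
            pairs += 1

    emb = EmbeddingMatrix(protein_ids, np.array(vectors))
    clusters = ClusterMap(member_to_cluster, representatives)
    hits = HitTable(pd.DataFrame(hit_rows))
    labels_observed = _labels_from_terms(obs_terms, hits, ont)
    labels_true = LabelMatrix(
        true_labels,
        source_term={p: phrog_term[hits.phrog_of(p)] for p in protein_ids},
        best_phrog={p: hits.phrog_of(p) for p in protein_ids},
    )

    # similarity edges between groups sharing a leaf (or root-only) category
    edges = []
    phrogs = list(phrog_centers)
    for i, a in enumerate(phrogs):
        for b in phrogs[i + 1:]:
            ca, cb = phrog_category[a], phrog_category[b]
            if ca is None or ca != cb:
                continue
            if rng.random() < cfg.similarity_edge_prob:
                edges.append(
                    (
                        a,
                        b,
                        float(10.0 ** rng.uniform(-20, -4)),
                        float(rng.uniform(0.81, 1.0)),
                    )
                )
    sim = SimilarityGraph(edges)

    return SynthDataset(
        config=cfg,
        ontology=ont,
        embeddings=emb,
        labels_true=labels_true,
        labels_observed=labels_observed,
        clusters=clusters,
        hits=hits,
        similarity=sim,
        category_centers=category_centers,
        phrog_centers=phrog_centers,
        phrog_category=phrog_category,
        background_center=background_center,
    )


def _labels_from_terms(
    terms: dict[str, str], hits: HitTable, ont: Ontology
) -> LabelMatrix:
    labels = {
        pid: frozenset() if term == UNKNOWN_TERM else frozenset(ont.map_term(term))
        for pid, term in terms.items()
    }
    return LabelMatrix(
        labels,
        source_term=dict(terms),
        best_phrog={pid: hits.phrog_of(pid) for pid in terms},
    )


def bayes_predictions(ds: SynthDataset) -> dict[str, set[str]]:
    """Nearest-center category assignment for every protein.

    Each protein goes to its nearest root center (the unannotated
    background counts as a root option) and, within the winning root, to
    the nearest child center when a child is closer than the root itself.
    """
    ont = ds.ontology
    roots = ont.roots()
    root_centers = np.stack([ds.category_centers[r] for r in roots] + [ds.background_center])
    X = ds.embeddings.vectors
    d_root = np.linalg.norm(X[:, None, :] - root_centers[None, :, :], axis=2)
    root_idx = np.argmin(d_root, axis=1)  # len(roots) == background

    predicted: list[set[str]] = []
    for i in range(len(X)):
        if root_idx[i] == len(roots):
            predicted.append(set())
            continue
        root = roots[root_idx[i]]
        assigned = {root}
        children = ont.children(root)
        if children:
            centers = np.stack(
                [ds.category_centers[c] for c in children]
                + [ds.category_centers[root]]
            )
            dist = np.linalg.norm(X[i] - centers, axis=1)
            j = int(np.argmin(dist))
            if j < len(children):
                assigned.add(children[j])
        predicted.append(assigned)
    return dict(zip(ds.embeddings.ids, predicted))


def bayes_reference(
    ds: SynthDataset, ids: list[str] | None = None
) -> dict[str, float]:
    """Per-category accuracy of nearest-center classification.

    The induced binary decision per category is scored against the
    noise-free truth (optionally restricted to ``ids``); this is the
    geometric performance ceiling trained models are compared against.
    """
    predicted = bayes_predictions(ds)
    ids = list(ds.embeddings.ids) if ids is None else list(ids)
    accuracy: dict[str, float] = {}
    for cat in (c.name for c in ds.ontology):
        truth = np.array([cat in ds.labels_true.labels_of(pid) for pid in ids])
        pred = np.array([cat in predicted[pid] for pid in ids])
        accuracy[cat] = float((truth == pred).mean())
    return accuracy


def dataclass_replace(cfg: SynthConfig, **changes) -> SynthConfig:
    from dataclasses import replace

    return replace(cfg, **changes)


def write_dataset(ds: SynthDataset, directory) -> None:
    """Write every on-disk dialect of the dataset into ``directory``."""
    from pathlib import Path

    from . import io
    from .ontology import save_ontology

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_ontology(ds.ontology, directory / "ontology.yaml")
    io.write_embeddings(ds.embeddings, directory / "embeddings.tsv")
    io.write_clusters(ds.clusters, directory / "clusters.tsv")
    io.write_hits(ds.hits, directory / "hits.tsv")
    io.write_similarity(ds.similarity, directory / "similarity.tsv")
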