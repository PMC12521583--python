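"""Readers and writers for every on-disk artifact the tool touches.

All tabular dialects are plain TSV with headers so they stay inspectable
with standard shell tools:

* embeddings      — ``id`` then ``e1..eD`` columns (HDF5 alternative for
  large dimensions);
* cluster map     — headerless two-column ``representative<TAB>member``
  (the MMseqs2 ``createtsv`` convention; the representative is also a
  member of its own cluster);
* profile-HMM hits — ``protein_id, phrog_id, annotation_term, e_value,
  coverage``, one row per search hit, best-hit filtered on read;
* group similarity — ``phrog_a, phrog_b, e_value, coverage`` undirected
  edges between homologous groups;
* predictions     — ``protein_id, prediction, <one confidence column per
  category>`` with ``NA`` where a model was gated off and the literal
  label ``unknown`` for proteins with no assignment.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "EmbeddingMatrix",
    "ClusterMap",
    "HitTable",
    "SimilarityGraph",
    "read_fasta",
    "write_fasta",
    "dedup_identical",
    "read_hits",
    "write_hits",
    "read_clusters",
    "write_clusters",
    "read_similarity",
    "write_similarity",
    "read_embeddings",
    "write_embeddings",
    "write_predictions",
    "read_predictions",
    "Embedder",
    "HashingEmbedder",
]

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZU*")

HIT_COLUMNS = ["protein_id", "phrog_id", "annotation_term", "e_value", "coverage"]
SIM_COLUMNS = ["phrog_a", "phrog_b", "e_value", "coverage"]

#: annotation term marking a homologous group without a known function
UNKNOWN_TERM = "unknown function"


@dataclass
class ProteinRecord:
    id: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - VALID_RESIDUES
            if bad:
                raise ValueError(
                    f"protein {self.id!r}: invalid residues {sorted(bad)}"
                )


class EmbeddingMatrix:
    """Fixed-dimension embedding vectors keyed by protein id."""

    def __init__(self, ids: Sequence[str], vectors: np.ndarray) -> None:
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2:
            raise ValueError("vectors must be 2-D (n proteins x D)")
        if len(ids) != vectors.shape[0]:
            raise ValueError("ids and vectors disagree on n")
        if vectors.shape[1] == 0:
            raise ValueError("embedding dimension must be positive")
        ids = [str(i) for i in ids]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate protein ids in embedding matrix")
        self.ids: list[str] = ids
        self.vectors: np.ndarray = vectors
        self._index = {pid: i for i, pid in enumerate(ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, pid: str) -> bool:
        return pid in self._index

    def get(self, pid: str) -> np.ndarray:
        return self.vectors[self._index[pid]]

    def subset(self, ids: Sequence[str]) -> "EmbeddingMatrix":
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise KeyError(f"{len(missing)} ids lack embeddings, e.g. {missing[:3]}")
        rows = [self._index[i] for i in ids]
        return EmbeddingMatrix(list(ids), self.vectors[rows])

    def matrix_for(self, ids: Sequence[str]) -> np.ndarray:
        return self.vectors[[self._index[i] for i in ids]]


class ClusterMap:
    """Protein -> homology-cluster assignment (each protein in exactly one)."""

    def __init__(
        self,
        member_to_cluster: dict[str, str],
        representatives: dict[str, str] | None = None,
    ) -> None:
        self.member_to_cluster = dict(member_to_cluster)
        self.representatives = dict(representatives or {})
        for cid, rep in self.representatives.items():
            if self.member_to_cluster.get(rep) != cid:
                raise ValueError(
                    f"representative {rep!r} is not a member of cluster {cid!r}"
                )
        self._members: dict[str, list[str]] = {}
        for member, cid in self.member_to_cluster.items():
            self._members.setdefault(cid, []).append(member)
        for mlist in self._members.values():
            mlist.sort()

    def cluster_of(self, pid: str) -> str:
        return self.member_to_cluster[pid]

    def members(self, cid: str) -> list[str]:
        return self._members[cid]

    def clusters(self) -> list[str]:
        return sorted(self._members)

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, pid: str) -> bool:
        return pid in self.member_to_cluster


class HitTable:
    """Best profile-HMM hit per protein (already best-hit filtered)."""

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = set(HIT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"hit table lacks columns {sorted(missing)}")
        if frame["protein_id"].duplicated().any():
            raise ValueError("hit table holds multiple rows for one protein")
        if (frame["e_value"] <= 0).any():
            raise ValueError("e-values must be positive")
        self.frame = frame.reset_index(drop=True)
        self._by_protein = self.frame.set_index("protein_id")

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, pid: str) -> bool:
        return pid in self._by_protein.index

    def proteins(self) -> list[str]:
        return list(self.frame["protein_id"])

    def phrog_of(self, pid: str) -> str:
        return str(self._by_protein.loc[pid, "phrog_id"])

    def term_of(self, pid: str) -> str:
        return str(self._by_protein.loc[pid, "annotation_term"])


class SimilarityGraph:
    """Undirected profile-profile similarity edges between homologous groups."""

    def __init__(self, edges: Iterable[tuple[str, str, float, float]]) -> None:
        self._adj: dict[str, dict[str, tuple[float, float]]] = {}
        n_self = 0
        for a, b, ev, cov in edges:
            a, b = str(a), str(b)
            if a == b:
                n_self += 1
                continue
            self._adj.setdefault(a, {})[b] = (float(ev), float(cov))
            self._adj.setdefault(b, {})[a] = (float(ev), float(cov))
        if n_self:
            warnings.warn(f"dropped {n_self} self-similarity edge(s)", stacklevel=2)

    def neighbors(self, phrog: str) -> dict[str, tuple[float, float]]:
        return self._adj.get(str(phrog), {})

    def component(self, phrog: str) -> set[str]:
        """Connected component containing ``phrog`` (including itself)."""
        phrog = str(phrog)
        seen = {phrog}
        stack = [phrog]
        while stack:
            node = stack.pop()
            for nb in self._adj.get(node, ()):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen

    def edges(self) -> list[tuple[str, str, float, float]]:
        out = []
        for a, nbrs in self._adj.items():
            for b, (ev, cov) in nbrs.items():
                if a < b:
                    out.append((a, b, ev, cov))
        return sorted(out)

    def n_edges(self) -> int:
        return len(self.edges())


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, dedup: bool = False) -> list[ProteinRecord]:
    """Read protein records; ids are the first whitespace token of headers."""
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            if dedup:
                continue
            raise ValueError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        out.append(rec)
    return out


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    seqs = [
        SeqRecord(Seq(rec.sequence or ""), id=rec.id, description="")
        for rec in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def dedup_identical(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Collapse 100%-identical sequences onto their first-seen record.

    Returns the unique records (input order) and a map sending every input
    id to its representative's id.
    """
    rep_by_seq: dict[str, str] = {}
    uniques: list[ProteinRecord] = []
    mapping: dict[str, str] = {}
    for rec in records:
        key = rec.sequence or ""
        if key in rep_by_seq:
            mapping[rec.id] = rep_by_seq[key]
        else:
            rep_by_seq[key] = rec.id
            mapping[rec.id] = rec.id
            uniques.append(rec)
    return uniques, mapping


# ---------------------------------------------------------------------------
# Hit tables


def read_hits(path, max_evalue: float = 0.001) -> HitTable:
    """Read a hit TSV and keep the best qualifying hit per protein.

    Rows with ``e_value`` >= ``max_evalue`` are discarded (strict "<");
    among the survivors the minimal e-value wins, ties broken by the
    lexicographically smaller ``phrog_id``.  Proteins with no qualifying
    hit are absent from the result.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "phrog_id": str})
    missing = set(HIT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    frame["e_value"] = pd.to_numeric(frame["e_value"], errors="raise")
    frame["coverage"] = pd.to_numeric(frame["coverage"], errors="raise")
    return best_hits(frame, max_evalue=max_evalue)


def best_hits(frame: pd.DataFrame, max_evalue: float = 0.001) -> HitTable:
    """Best-hit filter an in-memory multi-hit frame (same rules as read_hits)."""
    kept = frame[frame["e_value"] < max_evalue]
    kept = kept.sort_values(["protein_id", "e_value", "phrog_id"], kind="mergesort")
    kept = kept.drop_duplicates("protein_id", keep="first")
    return HitTable(kept[HIT_COLUMNS].reset_index(drop=True))


def write_hits(hits: HitTable, path) -> None:
    hits.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cluster maps


def read_clusters(path) -> ClusterMap:
    """Read a two-column representative<TAB>member cluster file."""
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["representative", "member"], dtype=str
    )
    member_to_cluster: dict[str, str] = {}
    representatives: dict[str, str] = {}
    for rep, member in frame.itertuples(index=False):
        if member in member_to_cluster and member_to_cluster[member] != rep:
            raise ValueError(
                f"{path}: member {member!r} listed under two representatives"
            )
        member_to_cluster[member] = rep
        representatives[rep] = rep
    # every representative implicitly belongs to its own cluster
    for rep in representatives:
        member_to_cluster.setdefault(rep, rep)
    return ClusterMap(member_to_cluster, representatives)


def write_clusters(clusters: ClusterMap, path) -> None:
    rows = []
    for cid in clusters.clusters():
        rep = clusters.representatives.get(cid, cid)
        for member in clusters.members(cid):
            rows.append((rep, member))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Similarity graphs


def read_similarity(path) -> SimilarityGraph:
    frame = pd.read_csv(path, sep="\t", dtype={"phrog_a": str, "phrog_b": str})
    missing = set(SIM_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return SimilarityGraph(
        (r.phrog_a, r.phrog_b, r.e_value, r.coverage)
        for r in frame.itertuples(index=False)
    )


def write_similarity(sim: SimilarityGraph, path) -> None:
    pd.DataFrame(sim.edges(), columns=SIM_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Embeddings


def read_embeddings(path) -> EmbeddingMatrix:
    """Read an embedding store (``.h5``/``.hdf5`` binary, else headered TSV)."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as fh:
            ids = [s.decode() for s in fh["ids"][()]]
            vectors = fh["vectors"][()]
        return EmbeddingMatrix(ids, vectors)
    frame = pd.read_csv(path, sep="\t", dtype={"id": str}, float_precision="round_trip")
    if "id" not in frame.columns:
        raise ValueError(f"{path}: embedding TSV lacks an 'id' column")
    ids = list(frame["id"])
    vectors = frame.drop(columns="id").to_numpy(dtype=np.float64)
    return EmbeddingMatrix(ids, vectors)


def write_embeddings(emb: EmbeddingMatrix, path) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as fh:
            fh.create_dataset(
                "ids", data=np.array([i.encode() for i in emb.ids])
            )
            fh.create_dataset("vectors", data=emb.vectors)
        return
    frame = pd.DataFrame(
        emb.vectors, columns=[f"e{i + 1}" for i in range(emb.dim)]
    )
    frame.insert(0, "id", emb.ids)
    # repr-round-trip float formatting keeps TSV stores lossless
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Predictions


def write_predictions(records, ontology, path) -> None:
    """Write prediction records as TSV.

    ``prediction`` holds semicolon-joined assigned category paths
    (``pvp>tail;cell wall depolymerase``) or the literal ``unknown``;
    one confidence column per ontology category holds the evaluated
    confidence or ``NA`` where the model was gated off.
    """
    cats = sorted(c.name for c in ontology)
    rows = []
    for rec in records:
        if rec.unknown:
            label = "unknown"
        else:
            # leaf-most assigned categories, rendered as root>...>leaf paths
            leaves = [
                c
                for c in rec.assigned
                if not any(
                    c in ontology.ancestors(other)
                    for other in rec.assigned
                    if other != c
                )
            ]
            paths = [
                ">".join(ontology.ancestors(leaf) + [leaf]) for leaf in sorted(leaves)
            ]
            label = ";".join(paths)
        row = {"protein_id": rec.protein_id, "prediction": label}
        for cat in cats:
            conf = rec.evaluated.get(cat)
            row[cat] = "NA" if conf is None else f"{conf:.6f}"
        rows.append(row)
    pd.DataFrame(rows, columns=["protein_id", "prediction"] + cats).to_csv(
        path, sep="\t", index=False
    )


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str})


# ---------------------------------------------------------------------------
# Embedder plug-in interface


class Embedder:
    """Contract for sequence -> fixed-size vector backends.

    Production embeddings come from protein language models run outside
    this package; implement :meth:`embed` to plug such a backend in.
    """

    dim: int

    def embed(self, records: Sequence[ProteinRecord]) -> EmbeddingMatrix:
        raise NotImplementedError


class HashingEmbedder(Embedder):
    """Deterministic sequence-hash embedding for tests and dry runs.

    Maps each sequence to a reproducible pseudo-random vector seeded from
    a BLAKE2 digest.  Carries no biological signal; identical sequences
    get identical vectors.
    """

    def __init__(self, dim: int = 64) -> None:
        if dim <= 0:
            raise ValueError("dim must be positive")
        self.dim = dim

    def embed(self, records: Sequence[ProteinRecord]) -> EmbeddingMatrix:
        vectors = np.empty((len(records), self.dim))
        for i, rec in enumerate(records):
            digest = hashlib.blake2b(
                (rec.sequence or rec.id).encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big") % 2**63)
            vectors[i] = rng.standard_normal(self.dim)
        return EmbeddingMatrix([r.id for r in records], vectors)


# ---------------------------------------------------------------------------
# Misc


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
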