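"""Hierarchical functional-category scheme for phage proteins.

Functional categories form a forest: several independent general groups
(phage virion proteins, lysis, DNA-associated, ...) each optionally carry
subcategories (tail, capsid, lysin, nuclease, ...).  Free-text annotation
terms from remote-homology searches are mapped onto categories; a term may
belong to several categories at once ("tail protein with lytic activity" is
both a tail protein and a cell wall depolymerase), and membership in a
subcategory always implies membership in its parents.

The reserved label ``unknown`` is never a category: it denotes the absence
of any category assignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Category",
    "Ontology",
    "OntologyError",
    "Override",
    "load_ontology",
    "save_ontology",
    "load_default_ontology",
    "normalize_term",
]

#: Directives a (term, category) override may carry.
OVERRIDE_DIRECTIVES = ("force_positive", "force_negative", "exclude")

_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Lowercase a term and collapse internal whitespace.

    Term matching is exact string equality after this normalization; no
    fuzzy matching is attempted, since annotation terms come from a
    controlled vocabulary of homologous-group labels.
    """
    return _WS.sub(" ", term.strip().lower())


class OntologyError(ValueError):
    """Structural violation in an ontology definition."""


@dataclass
class Category:
    """One functional category.

    Parameters
    ----------
    name
        Unique identifier within the ontology.
    parent
        Name of the parent category, or ``None`` for a root (general)
        category.
    terms
        Annotation terms assigned to this category.  The same term may
        appear under several categories.
    min_train_clusters
        Advisory floor on the number of positive homology clusters needed
        for a trainable model; categories below it are flagged nonviable
        at training time rather than rejected here.
    """

    name: str
    parent: str | None = None
    terms: set[str] = field(default_factory=set)
    min_train_clusters: int = 50

    def __post_init__(self) -> None:
        if not self.name:
            raise OntologyError("category name must be nonempty")
        if self.name == "unknown":
            raise OntologyError('"unknown" is reserved and cannot be a category')
        if self.min_train_clusters < 0:
            raise OntologyError("min_train_clusters must be nonnegative")
        self.terms = {normalize_term(t) for t in self.terms}


@dataclass(frozen=True)
class Override:
    """Per-(term, category) training directive.

    Used for terms whose category membership is too coarse or too
    ambiguous for label-derived training sets — e.g. regulators that
    should enter the positive set of a broader category only when their
    annotation allows it, or be excluded from both classes entirely.
    """

    term: str
    category: str
    directive: str

    def __post_init__(self) -> None:
        if self.directive not in OVERRIDE_DIRECTIVES:
            raise OntologyError(
                f"unknown override directive {self.directive!r}; "
                f"expected one of {OVERRIDE_DIRECTIVES}"
            )
        object.__setattr__(self, "term", normalize_term(self.term))


class Ontology:
    """A validated forest of functional categories with term mappings."""

    def __init__(
        self,
        categories: Iterable[Category],
        overrides: Iterable[Override] = (),
    ) -> None:
        self.categories: dict[str, Category] = {}
        for cat in categories:
            if cat.name in self.categories:
                raise OntologyError(f"duplicate category name {cat.name!r}")
            self.categories[cat.name] = cat
        self.overrides: list[Override] = list(overrides)
        self._validate()
        self._term_index: dict[str, set[str]] = {}
        for cat in self.categories.values():
            for term in cat.terms:
                self._term_index.setdefault(term, set()).add(cat.name)

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        for cat in self.categories.values():
            if cat.parent is not None and cat.parent not in self.categories:
                raise OntologyError(
                    f"category {cat.name!r} names missing parent {cat.parent!r}"
                )
        # cycle check: walk every parent chain with a visited set
        for name in self.categories:
            seen: set[str] = set()
            node: str | None = name
            while node is not None:
                if node in seen:
                    raise OntologyError(f"cycle in parent links through {node!r}")
                seen.add(node)
                node = self.categories[node].parent
        for ov in self.overrides:
            if ov.category not in self.categories:
                raise OntologyError(
                    f"override references unknown category {ov.category!r}"
                )

    # -- queries ----------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self.categories

    def __iter__(self):
        return iter(self.categories.values())

    def __len__(self) -> int:
        return len(self.categories)

    def roots(self) -> list[str]:
        return [c.name for c in self.categories.values() if c.parent is None]

    def children(self, name: str) -> list[str]:
        self._require(name)
        return [c.name for c in self.categories.values() if c.parent == name]

    def ancestors(self, name: str) -> list[str]:
        """Ancestor chain of ``name``, root first, excluding ``name``."""
        self._require(name)
        chain: list[str] = []
        node = self.categories[name].parent
        while node is not None:
            chain.append(node)
            node = self.categories[node].parent
        chain.reverse()
        return chain

    def depth(self, name: str) -> int:
        """0 for roots, 1 for their children, ..."""
        return len(self.ancestors(name))

    def map_term(self, term: str) -> set[str]:
        """All categories a term belongs to, closed under ancestry.

        Returns the union of every category whose term inventory contains
        the (normalized) term with all ancestors of those categories; the
        empty set when no category matches — such proteins remain
        candidates for the ``unknown`` label.
        """
        hits = self._term_index.get(normalize_term(term), set())
        out: set[str] = set()
        for name in hits:
            out.add(name)
            out.update(self.ancestors(name))
        return out

    def overrides_for(self, category: str) -> dict[str, str]:
        """term -> directive map for one category."""
        self._require(category)
        return {
            ov.term: ov.directive for ov in self.overrides if ov.category == category
        }

    def _require(self, name: str) -> None:
        if name not in self.categories:
            raise KeyError(f"unknown category {name!r}")

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "categories": {
                c.name: {
                    "parent": c.parent,
                    "terms": sorted(c.terms),
                    "min_train_clusters": c.min_train_clusters,
                }
                for c in self.categories.values()
            },
            "overrides": [
                {"term": o.term, "category": o.category, "directive": o.directive}
                for o in self.overrides
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Ontology":
        if "categories" not in data:
            raise OntologyError("ontology file lacks a 'categories' map")
        cats = []
        for name, spec in data["categories"].items():
            spec = spec or {}
            cats.append(
                Category(
                    name=str(name),
                    parent=spec.get("parent"),
                    terms=set(spec.get("terms", ())),
                    min_train_clusters=int(spec.get("min_train_clusters", 50)),
                )
            )
        ovs = [
            Override(ov["term"], ov["category"], ov["directive"])
            for ov in data.get("overrides", ()) or ()
        ]
        return cls(cats, ovs)


def ancestors(cat: str, ont: Ontology) -> list[str]:
    """Functional alias for :meth:`Ontology.ancestors`."""
    return ont.ancestors(cat)


def map_term(term: str, ont: Ontology) -> set[str]:
    """Functional alias for :meth:`Ontology.map_term`."""
    return ont.map_term(term)


def load_ontology(path) -> Ontology:
    """Load and validate an ontology from a YAML/JSON file.

    The file holds a top-level ``categories`` map
    ``name -> {parent, terms, min_train_clusters}`` and an optional
    ``overrides`` list of ``{term, category, directive}`` entries.
    Raises :class:`OntologyError` on duplicate names, dangling parents,
    parent-link cycles or overrides naming unknown categories.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise OntologyError(f"{path}: not an ontology mapping")
    return Ontology.from_dict(data)


def save_ontology(ont: Ontology, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(ont.to_dict(), fh, sort_keys=True)


def load_default_ontology() -> Ontology:
    """The ontology skeleton shipped with the package.

    Covers the category hierarchy used throughout the documentation
    (structural proteins, lysis, DNA-associated, depolymerases,
    transferases, packaging) with a small representative term inventory.
    Real analyses should supply a complete ontology file.
    """
    ref = resources.files("phannot").joinpath("data/default_ontology.yaml")
    with resources.as_file(ref) as path:
        return load_ontology(path)
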