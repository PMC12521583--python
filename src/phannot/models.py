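"""Calibrated binary category models and the parent-gated cascade.

One binary classifier is trained per functional category — an RBF-kernel
support vector machine on the embedding vectors, wrapped in sigmoid (Platt)
calibration so its output is a probability ("confidence").  Inference walks
the ontology from the roots: a subcategory model is evaluated only for
proteins whose parent confidence already clears the gate, and a category is
assigned only when its own confidence clears the assignment threshold AND
its parent is assigned.  Proteins clearing no root model receive the
reserved ``unknown`` label.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from . import __version__
from .datasets import CategoryDataset
from .io import EmbeddingMatrix
from .ontology import Ontology, load_ontology, save_ontology

__all__ = [
    "CalibratedSVC",
    "BinaryModel",
    "TrainedCascade",
    "PredictionRecord",
    "train_binary",
    "train_cascade",
    "predict_cascade",
    "assign_from_confidences",
    "top_confidence",
]


class CalibratedSVC(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM with Platt-calibrated probability output.

    scikit-learn-compatible estimator: ``fit(X, y)`` on a binary target,
    then ``predict_proba`` returns calibrated probabilities.  Calibration
    is a sigmoid fitted by internal ``cv``-fold cross-validation on the
    training data, so confidences are usable as probabilities without a
    separate calibration split.

    Parameters
    ----------
    C : float
        SVM regularization strength.
    gamma : str or float
        RBF kernel width; ``"scale"`` uses 1 / (D * Var[X]).
    class_weight : dict, "balanced" or None
        Per-class weight multipliers on C.
    cv : int
        Folds for the internal calibration cross-validation.
    standardize : bool
        Standardize features per dimension, fitted on the training data
        only.  Off by default: embeddings arrive on a common scale and
        the "scale" gamma absorbs overall variance.
    random_state : int
        Seed forwarded to the underlying SVM.
    """

    def __init__(
        self,
        C: float = 1.0,
        gamma: str | float = "scale",
        class_weight: dict | str | None = None,
        cv: int = 5,
        standardize: bool = False,
        random_state: int = 0,
    ) -> None:
        self.C = C
        self.gamma = gamma
        self.class_weight = class_weight
        self.cv = cv
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y) -> "CalibratedSVC":
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        svc = SVC(
            kernel="rbf",
            C=self.C,
            gamma=self.gamma,
            class_weight=self.class_weight,
            random_state=self.random_state,
        )
        base = (
            make_pipeline(StandardScaler(), svc) if self.standardize else svc
        )
        n_min = int(min(np.bincount(np.searchsorted(classes, y))))
        cv = max(2, min(self.cv, n_min))  # never more folds than minority size
        self.calibrated_ = CalibratedClassifierCV(base, method="sigmoid", cv=cv)
        self.calibrated_.fit(X, y)
        self.classes_ = self.calibrated_.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.calibrated_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def confidence(self, X) -> np.ndarray:
        """Calibrated probability of the positive class (label 1)."""
        proba = self.predict_proba(X)
        pos_col = int(np.where(self.classes_ == 1)[0][0])
        return proba[:, pos_col]


@dataclass
class BinaryModel:
    """A fitted category model plus its training metadata."""

    category: str
    estimator: CalibratedSVC
    n_pos: int
    n_neg: int
    split_hash: str
    hyperparameters: dict = field(default_factory=dict)

    def confidence(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.confidence(X)


@dataclass
class PredictionRecord:
    """Cascade output for one protein.

    ``evaluated`` holds a confidence for every category whose model ran
    (including ones below threshold); categories gated off are absent.
    ``assigned`` is ancestor-closed; ``unknown`` means no assignment.
    """

    protein_id: str
    evaluated: dict[str, float]
    assigned: frozenset[str]
    unknown: bool


def train_binary(
    ds: CategoryDataset,
    emb: EmbeddingMatrix,
    C: float = 1.0,
    gamma: str | float = "scale",
    cv: int = 5,
    random_state: int = 0,
) -> BinaryModel:
    """Fit one category model on the training side of its dataset.

    Only train-side proteins are used; class weights are the dataset's
    inverse-frequency weights recomputed on the train side.
    """
    pos = ds.train_positives()
    neg = ds.train_negatives()
    if not pos or not neg:
        raise ValueError(
            f"category {ds.category!r}: empty training class "
            f"({len(pos)} pos / {len(neg)} neg on the train side)"
        )
    ids = pos + neg
    X = emb.matrix_for(ids)
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    total = len(pos) + len(neg)
    weight = {1: total / len(pos), 0: total / len(neg)}
    est = CalibratedSVC(
        C=C, gamma=gamma, class_weight=weight, cv=cv, random_state=random_state
    )
    est.fit(X, y)
    return BinaryModel(
        category=ds.category,
        estimator=est,
        n_pos=len(pos),
        n_neg=len(neg),
        split_hash=ds.split.content_hash(),
        hyperparameters={
            "kernel": "rbf",
            "C": C,
            "gamma": gamma,
            "calibration": "sigmoid",
            "cv": cv,
            "random_state": random_state,
        },
    )


class TrainedCascade:
    """Ontology snapshot plus one fitted binary model per viable category."""

    def __init__(
        self,
        ontology: Ontology,
        models: dict[str, BinaryModel],
        threshold: float = 0.5,
    ) -> None:
        if not 0.0 < threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        self.ontology = ontology
        self.models = dict(models)
        self.threshold = threshold
        for name in self.models:
            ontology._require(name)

    def categories(self) -> list[str]:
        """Modeled categories in root-first (parents before children) order."""
        return sorted(self.models, key=lambda c: (self.ontology.depth(c), c))

    @property
    def dim(self) -> int:
        any_model = next(iter(self.models.values()))
        return int(any_model.estimator.n_features_in_)

    # -- inference --------------------------------------------------------

    def predict(
        self,
        emb: EmbeddingMatrix,
        threshold: float | None = None,
        gate_threshold: float | None = None,
    ) -> list[PredictionRecord]:
        """Run the parent-gated cascade over every protein in ``emb``.

        Root models are evaluated for all proteins.  A child model is
        evaluated only where the parent confidence reaches the gate
        (default: the assignment threshold).  Assignment requires the
        category's own confidence >= threshold and an assigned parent.
        """
        assign_t = self.threshold if threshold is None else float(threshold)
        gate_t = assign_t if gate_threshold is None else float(gate_threshold)
        if not 0.0 < assign_t < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if emb.dim != self.dim:
            raise ValueError(
                f"embedding dimension {emb.dim} != model dimension {self.dim}"
            )
        n = len(emb)
        conf: dict[str, np.ndarray] = {}  # category -> per-protein confidence
        mask: dict[str, np.ndarray] = {}  # category -> evaluated mask
        for cat in self.categories():
            parent = self.ontology.categories[cat].parent
            if parent is None:
                sel = np.ones(n, dtype=bool)
            elif parent in conf:
                sel = mask[parent] & (conf[parent] >= gate_t)
            else:
                # nonviable parent with no model: children are skipped
                warnings.warn(
                    f"skipping {cat!r}: parent {parent!r} has no model",
                    stacklevel=2,
                )
                continue
            values = np.full(n, np.nan)
            if sel.any():
                values[sel] = self.models[cat].confidence(emb.vectors[sel])
            conf[cat] = values
            mask[cat] = sel
        records: list[PredictionRecord] = []
        for i, pid in enumerate(emb.ids):
            evaluated = {
                cat: float(conf[cat][i]) for cat in conf if mask[cat][i]
            }
            assigned = assign_from_confidences(evaluated, self.ontology, assign_t)
            records.append(
                PredictionRecord(
                    protein_id=pid,
                    evaluated=evaluated,
                    assigned=frozenset(assigned),
                    unknown=not assigned,
                )
            )
        return records

    # -- persistence ------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_ontology(self.ontology, directory / "ontology.yaml")
        (directory / "models").mkdir(exist_ok=True)
        meta: dict = {
            "version": __version__,
            "threshold": self.threshold,
            "categories": {},
        }
        for name, model in self.models.items():
            fname = f"models/{name.replace(' ', '_').replace('/', '_')}.joblib"
            joblib.dump(model.estimator, directory / fname)
            meta["categories"][name] = {
                "file": fname,
                "n_pos": model.n_pos,
                "n_neg": model.n_neg,
                "split_hash": model.split_hash,
                "hyperparameters": model.hyperparameters,
            }
        with open(directory / "metadata.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, directory) -> "TrainedCascade":
        directory = Path(directory)
        ontology = load_ontology(directory / "ontology.yaml")
        with open(directory / "metadata.json", "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        models = {}
        for name, entry in meta["categories"].items():
            est = joblib.load(directory / entry["file"])
            models[name] = BinaryModel(
                category=name,
                estimator=est,
                n_pos=entry["n_pos"],
                n_neg=entry["n_neg"],
                split_hash=entry["split_hash"],
                hyperparameters=entry["hyperparameters"],
            )
        return cls(ontology, models, threshold=meta.get("threshold", 0.5))


def train_cascade(
    datasets: dict[str, CategoryDataset],
    emb: EmbeddingMatrix,
    ontology: Ontology,
    threshold: float = 0.5,
    random_state: int = 0,
    **hyperparameters,
) -> TrainedCascade:
    """Train a binary model for every viable category dataset."""
    models: dict[str, BinaryModel] = {}
    for name, ds in sorted(datasets.items()):
        if not ds.viable:
            warnings.warn(f"skipping nonviable category {name!r}", stacklevel=2)
            continue
        models[name] = train_binary(
            ds, emb, random_state=random_state, **hyperparameters
        )
    if not models:
        raise ValueError("no viable category could be trained")
    return TrainedCascade(ontology, models, threshold=threshold)


def predict_cascade(
    cascade: TrainedCascade,
    emb: EmbeddingMatrix,
    threshold: float = 0.5,
    gate_threshold: float | None = None,
) -> list[PredictionRecord]:
    """Functional alias for :meth:`TrainedCascade.predict`."""
    return cascade.predict(emb, threshold=threshold, gate_threshold=gate_threshold)


def assign_from_confidences(
    evaluated: dict[str, float], ontology: Ontology, threshold: float
) -> set[str]:
    """Pure assignment rule: threshold plus parent gating.

    A category is assigned iff its confidence reaches the threshold and
    its parent (when it has one) is itself assigned.  The result is
    therefore ancestor-closed by construction.
    """
    assigned: set[str] = set()
    for cat in sorted(evaluated, key=lambda c: (ontology.depth(c), c)):
        if evaluated[cat] < threshold:
            continue
        parent = ontology.categories[cat].parent
        if parent is None or parent in assigned:
            assigned.add(cat)
    return assigned


def top_confidence(rec: PredictionRecord, ontology: Ontology) -> float:
    """Confidence of the highest-level (closest-to-root) assigned category.

    0.0 for unknown records; ties between equal-depth assignments resolve
    to the larger confidence.
    """
    if rec.unknown:
        return 0.0
    best_depth = min(ontology.depth(c) for c in rec.assigned)
    return max(
        rec.evaluated[c]
        for c in rec.assigned
        if ontology.depth(c) == best_depth
    )
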