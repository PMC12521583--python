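# Methods

## Problem setting

Phage proteins are annotated by remote-homology search against profile
HMMs of homologous protein families; each family carries a free-text
annotation term or "unknown function". `phannot` treats functional
annotation as hierarchical multi-label classification on fixed-size
embedding vectors: one independent binary model per functional category,
assembled into a parent-gated cascade. Embeddings are consumed, not
computed — any backend implementing the `Embedder` contract (sequence
list → matrix) can be plugged in; the shipped `HashingEmbedder` is a
deterministic stand-in for tests and dry runs and carries no biological
signal.

## Ontology and labeling

Categories form a forest; a category holds a set of annotation terms and
an optional parent. Term matching is exact string equality after
lowercasing and whitespace collapsing — terms come from a controlled
vocabulary, so fuzzy matching would only add noise. A term may belong to
several categories, and `map_term` closes the result under ancestry, so
label sets are always ancestor-closed. Per-(term, category) overrides
(`force_positive`, `force_negative`, `exclude`) handle terms whose
membership is too coarse for clean training sets, e.g. regulators that
belong in a broad DNA-associated positive set only when their annotation
allows it.

A protein's labels come from its single best profile-HMM hit, kept only
when its e-value is strictly below 0.001; among qualifying hits the
smallest e-value wins, with ties broken toward the lexicographically
smaller family id (the tie-break is this package's choice; any
deterministic rule would do). Proteins whose best hit is an
unknown-function family keep the family id for bookkeeping: such a
protein counts as *rescued* when its family has a similarity edge
(e-value < 0.001 AND coverage strictly > 0.80) to an annotated family,
or when an annotated protein shares its homology cluster. When both
rules apply the similarity rescue is reported, being a property of the
protein itself. Rescue is reporting only and never feeds training.

## Per-category training sets

The anti-noise and anti-leakage machinery, per category:

1. **Candidate universe** — all annotated proteins for a root (general)
   category; only parent-labeled proteins for a subcategory.
2. **Positives** — proteins labeled with the category (plus
   `force_positive` overrides).
3. **Exclusions** — proteins whose labels carry no subcategory
   information below the parent (annotation too general to place),
   override-excluded terms, and every protein of a *conflicted* cluster
   (one containing both a positive- and a negative-definition protein
   for this category).
4. **Negatives** — the remaining candidates; for root categories they
   are downsampled to one per homology cluster (diversifies the negative
   class and narrows the class-size gap). The survivor is the cluster
   representative when eligible, else the smallest member id — a
   deterministic choice that keeps runs reproducible without an extra
   RNG stream.

Class imbalance is corrected with inverse-frequency weights
w(k) = 1 / (n_k / n). Proteins with empty label sets are invisible to
training. A category is flagged nonviable (trained models are skipped,
with a warning) below a floor of positive clusters — default 50,
motivated by the observation that categories trained on a few dozen
clusters produce unreliable models; the synthetic ontology lowers the
floor to 2 because its categories are deliberately small.

Train/test splitting assigns whole homology clusters to sides
(`round(0.8 · n_clusters)` train), so no cluster contributes proteins to
both. One global split is shared by all categories per run by default,
keeping cross-category predictions comparable; per-category resplitting
is available by calling `split_clusters` per category.

## Models and inference

Each category model is an RBF-kernel SVM (`C = 1.0`,
`gamma = 1/(D · Var[X])`, i.e. scikit-learn's `"scale"`), wrapped in
sigmoid (Platt) calibration fitted by internal 5-fold cross-validation
on the training side, so outputs are usable probabilities. The fold
count drops automatically when a class has fewer members than folds
(never below 2). Embeddings are used as-is — protein-language-model
embeddings are already on a common scale and the RBF `"scale"` gamma
absorbs overall variance; per-dimension standardization can be added by
the caller if an embedding backend needs it.

Inference walks the ontology root-first. Root models score every
protein; a child model is evaluated only where the parent's confidence
reaches the gate, and a category is assigned when its own confidence
reaches the assignment threshold and its parent is assigned. Gate and
assignment thresholds default to the same value (0.5; stringent preset
0.95) but are separate knobs, since evaluation-gating and assignment are
logically distinct decisions. Assigned sets are ancestor-closed by
construction; an empty assigned set is exactly the `unknown` label. The
headline confidence of a record is the confidence of its
closest-to-root assigned category.

Determinism: for fixed seeds and inputs the whole pipeline —
generation, splitting, training, prediction, TSV serialization — is
byte-reproducible. TSV embedding stores are written with
round-trip-exact float formatting and read with pandas'
`float_precision="round_trip"`.

## Evaluation

Precision, sensitivity and F1 are reported per category as functions of
the confidence threshold. Precision is *undefined* (NaN), not zero,
where nothing is assigned, and undefined values are excluded from
averages. The evaluation universe per category mirrors its training-set
definition: annotated proteins for a root category, parent-labeled
proteins carrying subcategory information for a child — a child
prediction cannot be validated against an annotation that stops at the
parent. Unlike training, negatives are not downsampled for evaluation.
Metrics are protein-level by default; cluster-level counts are available
through the consistency audit.

The consistency audit bins clusters of size ≥ 2 by agreement of their
members' assigned sets: `identical`, `identical_with_unknowns`,
`partial_overlap` (distinct assignments whose root-category sets
intersect) and `differing` (disjoint root sets). With more than two
distinct assignments, `partial_overlap` requires every pair to share a
root — the strictest reading of "sharing at least one general
function"; all-unknown clusters are counted separately and singletons
skipped.

## Holdout-homolog robustness

Cluster-level splitting cannot separate remote homologs that
sequence-sequence clustering misses. The stress test removes one
homologous family *and every family similar to it* (direct similarity
neighbors by default; the whole connected component as an option) from
training entirely — dropped, not moved to negatives — retrains the
category model on everything else (no 80/20 split: the held-out family
is the test set), and scores on the held-out proteins. Families are
sampled uniformly (seeded) among those with at least 5 category-labeled
proteins. Every held-out protein is a true positive by construction, so
precision is 1 where anything is predicted and undefined (recorded as
missing) where nothing is — degradation therefore lands on sensitivity,
which is exactly the behavior the protocol probes.

## Synthetic benchmark

The generator plants the geometry the method relies on: root-category
centers `delta = 6` apart (on coordinate axes, background at the
origin), child centers offset `sigma_c = 1.5` from their parent along
random unit directions, family (PHROG-like) centers offset 0.3 from
their category center, and proteins scattered with radius
`sigma_w = 0.15` around their family center. `delta > sigma_c >
sigma_w` makes categories separable: the nearest-center (Bayes
reference) classifier exceeds 99% accuracy at the default
configuration and is the ceiling trained models are compared against.

Defaults (one benchmark, chosen once): D = 64 (the framework is
dimension-agnostic; small D keeps the suite fast), 3 roots × 2 children,
10 families per leaf plus 2 parent-only families per root and 4
background families, 15–25 proteins per family (≈ 1.4k proteins, ≈ 70
clusters — one homology cluster per family), 10% of leaf families
unknown-function, 2% label noise (a protein's observed term swapped to
another leaf's term), similarity edges with probability 0.5 between
families of the same category (coverage drawn in (0.81, 1.0), so edges
qualify for rescue), and an optional count of deliberately conflicted
clusters for exercising the exclusion rule. Noise and unknown-function
rates are kept modest because the real pipeline's inputs are
best-hit-filtered annotations, not raw noisy text.

The generator emulates *structure*, not biology: real embedding spaces
are anisotropic, related functions share substructure, and family sizes
are heavy-tailed. Passing the benchmark shows the machinery —
labeling, splitting, training, gating, holdout — is correct, not that
any particular accuracy carries over to real embeddings.

## Numerical and degenerate-input choices

* Splits guarantee both sides nonempty (≥ 2 clusters required).
* Training requires both classes nonempty on the train side; calibration
  folds adapt to the minority class size.
* An infeasible generator configuration (more root centers than
  dimensions, or violated spread ordering) raises unless explicitly
  forced for degenerate-geometry experiments.
* Equal e-value hits, negative-downsampling survivors and iteration
  order are all resolved deterministically (documented tie-breaks, no
  hidden RNG).

## Known limitations

* Real protein-language-model inference, HMM searches, clustering and
  gene calling are all external; the package consumes their outputs.
* The shipped default ontology is a skeleton covering the documented
  category hierarchy with a representative term inventory; production
  use requires a complete ontology file.
* Metrics against observed labels inherit annotation noise; the
  synthetic benchmark scores against planted truth instead, which real
  datasets do not offer.
* The holdout protocol retrains one binary model per iteration;
  protocol cost is linear in iterations × categories.
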