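import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from phannot.datasets import split_clusters
from phannot.ontology import Category, Ontology, Override
from phannot.pipeline import fit_pipeline
from phannot.synthetic import generate


@pytest.fixture(scope="session")
def toy_ontology():
    """pvp > {tail, capsid}; lysis > {lysin}; shared-term multi-membership."""
    return Ontology(
        [
            Category("pvp", terms={"phage virion protein"}, min_train_clusters=0),
            Category("tail", parent="pvp",
                     terms={"tail protein", "tail protein with lytic activity"},
                     min_train_clusters=0),
            Category("capsid", parent="pvp", terms={"major capsid protein"},
                     min_train_clusters=0),
            Category("lysis", terms={"lysis protein"}, min_train_clusters=0),
            Category("lysin", parent="lysis", terms={"endolysin"},
                     min_train_clusters=0),
            Category("cell wall depolymerase",
                     terms={"tail protein with lytic activity"},
                     min_train_clusters=0),
        ],
        overrides=[Override("regulator-like protein", "lysis", "exclude")],
    )


@pytest.fixture(scope="session")
def synth():
    """The default synthetic benchmark, generated once per session."""
    return generate(seed=20240)


@pytest.fixture(scope="session")
def synth_split(synth):
    return split_clusters(synth.clusters, train_fraction=0.8, seed=20240)


@pytest.fixture(scope="session")
def trained_cascade(synth, synth_split):
    """Cascade trained on the observed (noisy) labels of the benchmark."""
    return fit_pipeline(
        synth.labels_observed,
        synth.clusters,
        synth.ontology,
        synth.embeddings,
        synth_split,
        random_state=20240,
    )
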