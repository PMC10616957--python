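import numpy as np
import pytest

from cytoagi.taxonomy import build_default_taxonomy, boolean_gate
from cytoagi.simdata import default_panel_model, simulate_sample, SampleSpec
from cytoagi.database import init_database, classify_and_merge


@pytest.fixture(scope="session")
def tax():
    return build_default_taxonomy()


@pytest.fixture(scope="session")
def model(tax):
    return default_panel_model(tax)


@pytest.fixture(scope="session")
def small_sample(model):
    """One 20k-event labelled sample shared by fast unit tests."""
    return simulate_sample(model, SampleSpec(n_events=20_000, seed=321,
                                             sample_id="unit"))


@pytest.fixture(scope="session")
def small_db(tax, model):
    """Two-file reference database at unit-test scale."""
    db = None
    for s in (51, 52):
        em, _ = simulate_sample(model, SampleSpec(n_events=30_000, seed=s,
                                                  sample_id=f"db-{s}"))
        labels = boolean_gate(em, tax).labels
        db = init_database(em, labels, tax) if db is None \
            else classify_and_merge(db, em, labels)
    return db
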