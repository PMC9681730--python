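import numpy as np
import pytest

from protacdeg.dataset import apply_labels, read_manifest
from protacdeg.featurize import build_encoding_table
from protacdeg.synthdata import SynthSpec, generate_dataset, smiles_corpus
from protacdeg.train_eval import prepare_samples


@pytest.fixture(scope="session")
def encoding_table():
    return build_encoding_table(smiles_corpus(500, seed=3))


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small linker-band dataset shared across tests (60 records)."""
    out = tmp_path_factory.mktemp("tiny")
    spec = SynthSpec(n_records=60, seed=11, active_rule="linker_band")
    manifest = generate_dataset(spec, out)
    return {"dir": out, "manifest": manifest, "spec": spec}


@pytest.fixture(scope="session")
def tiny_records(tiny_dataset):
    return apply_labels(read_manifest(tiny_dataset["manifest"]))


@pytest.fixture(scope="session")
def tiny_samples(tiny_dataset, tiny_records, encoding_table):
    return prepare_samples(
        tiny_records, tiny_dataset["dir"], encoding_table, max_len=60
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
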