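import numpy as np
import pytest

from crisprtl.core_data import ALPHABET, Dataset, GuideRecord
from crisprtl.biofeatures import attach_biofeatures, attach_energy_scores, gc_proxy_energy
from crisprtl.models import ModelSpec
from crisprtl.synthetic import SimConfig, simulate_pair


def random_guide21(rng) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=21))


def random_context30(rng) -> str:
    letters = list(rng.integers(0, 4, size=30))
    letters[25] = letters[26] = ALPHABET.index("G")
    return "".join(ALPHABET[i] for i in letters)


def make_dataset(n, seed=0, conditions=("WT",), with_features=True) -> Dataset:
    """Random guide dataset with complete efficiencies under each condition."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        ctx = random_context30(rng)
        effs = {c: float(rng.uniform()) for c in conditions}
        records.append(GuideRecord(id=f"g{i}", guide21=ctx[4:25], context30=ctx,
                                   efficiencies=effs))
    ds = Dataset(records=records, name=f"random{seed}",
                 condition_labels=list(conditions))
    if with_features:
        attach_biofeatures(ds)
        attach_energy_scores(ds, gc_proxy_energy)
    return ds


@pytest.fixture(scope="session")
def tiny_rnn_spec():
    return ModelSpec(kind="rnn", embedding_dim=4, recurrent_units=6,
                     dense_layers=(8, 4))


@pytest.fixture(scope="session")
def tiny_cnn_spec():
    return ModelSpec(kind="cnn", conv_filters=5, cnn_dense=(6, 4))


@pytest.fixture(scope="session")
def small_pair():
    """A small simulated source/target pair shared across tests."""
    return simulate_pair(SimConfig(n_source=200, n_target=80, seed=11))
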