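import numpy as np
import pytest

from calpsite import Hyperparameters, train
from calpsite import synthetic_data as sd
from calpsite.encoders import ALPHABET
from calpsite.sequence_io import STANDARD_RESIDUES, LabeledDataset, Protein


#: Small training budget for tests that only need a working model, not a good one.
FAST_HYPER = Hyperparameters(
    branch_layers=((4,), (8,), (8,), (4,)),
    merged_layers=(8,),
    epochs=5,
)


def random_window(rng: np.random.Generator, length: int = 30) -> str:
    """A random peptide window with pad symbols only as a contiguous prefix/suffix."""
    left = int(rng.integers(0, 6))
    right = int(rng.integers(0, 6))
    core = rng.choice(list(STANDARD_RESIDUES), size=length - left - right)
    return "-" * left + "".join(core) + "-" * right


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def synth_dataset() -> LabeledDataset:
    """Balanced planted-motif window set at generator defaults."""
    return sd.generate_training_set(seed=7)


@pytest.fixture(scope="session")
def tiny_dataset() -> LabeledDataset:
    """A very small balanced window set for fast training smoke tests."""
    return sd.generate_training_set(n_positive=30, n_negative=30, seed=5)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """A quickly trained model; adequate for contract tests, not for accuracy."""
    return train(tiny_dataset, hyper=FAST_HYPER, seed=1)


@pytest.fixture(scope="session")
def synth_corpus():
    """Proteins with planted sites plus near/far variants."""
    proteins, sites = sd.generate_proteins(30, sites_per_protein=1, seed=13)
    variants = sd.generate_variants(proteins, sites, n_near=40, n_far=40, seed=14)
    return proteins, sites, variants
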