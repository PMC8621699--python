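import numpy as np
import pytest

from lgfc.io_data import InteractionDataset, SequenceRecord
from lgfc.synthetic_fixtures import SyntheticSpec, generate, worked_toy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    return worked_toy()


@pytest.fixture(scope="session")
def small_synthetic():
    """A small labelled synthetic dataset with a strong planted signal."""
    return generate(SyntheticSpec(n_pairs=200, n_lnc=30, n_prot=20, seed=7, effect=1.0))


def random_rna(rng, length, with_n=False):
    alphabet = "ACGUN" if with_n else "ACGU"
    return "".join(rng.choice(list(alphabet), size=length))


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


@pytest.fixture
def tiny_registry():
    recs = [
        SequenceRecord(id="r1", seq="ACGU" * 60, kind="rna"),
        SequenceRecord(id="r2", seq="AUGC" * 75, kind="rna"),
        SequenceRecord(id="p1", seq="MKVLAT" * 12, kind="protein"),
        SequenceRecord(id="p2", seq="WYHRKDE" * 10, kind="protein"),
    ]
    return {r.id: r for r in recs}


@pytest.fixture
def tiny_dataset(tiny_registry):
    pairs = [("r1", "p1", 1), ("r2", "p2", 1), ("r1", "p2", 0), ("r2", "p1", 0)]
    return InteractionDataset(pairs=pairs, registry=tiny_registry, name="tiny")
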