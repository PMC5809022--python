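import numpy as np
import pytest

from sucbigram.io import ProteinProfile
from sucbigram.synthetic import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_profile(rng, length, protein_id="p1", sequence=None):
    """Random valid ProteinProfile with row-stochastic-ish matrices."""
    if sequence is None:
        sequence = "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
    pssm = rng.dirichlet(np.ones(20), size=length)
    sspre = rng.dirichlet(np.ones(3), size=length)
    return ProteinProfile(protein_id, sequence, pssm, sspre)


@pytest.fixture
def small_dataset():
    """Small planted-signal dataset shared across tests."""
    cfg = SynthConfig(n_proteins=30, seed=11, effect_size=1.0)
    return generate_dataset(cfg)
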