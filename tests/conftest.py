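import numpy as np
import pytest
from hypothesis import settings

from locustmeth import SequenceRecord, UnigeneSetSpec, generate_unigene_set

# derandomized property tests; no example database on disk
settings.register_profile("default", database=None, deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def planted_unigenes():
    """A moderate two-population unigene set shared across tests."""
    spec = UnigeneSetSpec(n_genes=600, seed=20)
    return generate_unigene_set(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_record(rng, length, gc=0.5, n_frac=0.0, seq_id="r"):
    """An i.i.d. test sequence, optionally salted with Ns."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(list("ACGT"), size=length, p=p)
    if n_frac > 0:
        mask = rng.random(length) < n_frac
        bases[mask] = "N"
    return SequenceRecord(id=seq_id, residues="".join(bases))
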