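import numpy as np
import pytest

from tvcurve import NussinovBackend, RnaRecord


@pytest.fixture(scope="session")
def backend():
    return NussinovBackend()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_record(rng, length, rec_id="rec", backend=None):
    """A random RNA record, folded with the fallback backend."""
    seq = "".join(rng.choice(list("ACGU"), size=length))
    backend = backend or NussinovBackend()
    return RnaRecord(id=rec_id, sequence=seq, structure=backend.fold(seq))
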