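import numpy as np
import pytest
from hypothesis import settings

from ctsdyn import enm, synthetic as syn

settings.register_profile("deterministic", derandomize=True,
                          database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ring_and_info():
    """Default seven-subunit synthetic ring (seed 0)."""
    return syn.make_ring(seed=0)


@pytest.fixture(scope="session")
def two_state(ring_and_info):
    """T / R'' endpoint pair with the default planted tail motion."""
    ring, info = ring_and_info
    st_t, st_r, planted = syn.make_two_state(ring, info, seed=1)
    return st_t, st_r, planted, info


@pytest.fixture(scope="session")
def dimer_models():
    """Two-node ENMs with different equilibrium separations."""
    t = enm.build_enm(np.array([[0.0, 0, 0], [5.0, 0, 0]]), cutoff=20.0)
    r = enm.build_enm(np.array([[0.0, 0, 0], [7.0, 0, 0]]), cutoff=20.0)
    return t, r


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path
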