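import numpy as np
import pytest

from bsikit.chem import Fingerprint
from bsikit.synthetic import UniverseConfig, generate_universe


def make_fp(bits, n_bits=None, radius=2, kind="morgan"):
    arr = np.asarray(bits, dtype=np.uint8)
    return Fingerprint(bits=arr, n_bits=n_bits or arr.size, radius=radius, kind=kind)


def tanimoto_set_oracle(a, b):
    """Brute-force Tanimoto via python set operations."""
    sa = {i for i, v in enumerate(a) if v}
    sb = {i for i, v in enumerate(b) if v}
    union = sa | sb
    if not union:
        raise ValueError("both fingerprints empty")
    return len(sa & sb) / len(union)


@pytest.fixture(scope="session")
def small_universe():
    """A small fingerprint-mode universe shared by read-only tests."""
    return generate_universe(UniverseConfig(
        targets_per_group=3, actives_per_target=15, inactives_per_target=4,
        pool_per_active=15, seed=42))


@pytest.fixture(scope="session")
def smiles_universe():
    return generate_universe(UniverseConfig(
        mode="smiles", targets_per_group=2, actives_per_target=10,
        inactives_per_target=4, pool_per_active=8, seed=42))
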