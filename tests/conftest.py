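import numpy as np
import pytest

from sas6screen import pharmacophore, synthetic


@pytest.fixture(scope="session")
def spec():
    return synthetic.SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def toy_interface(spec):
    return synthetic.make_toy_interface(spec)


@pytest.fixture(scope="session")
def interface_model(toy_interface):
    s, _ = toy_interface
    return pharmacophore.derive_model(s, "B", "A")


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00 11.50           C
ATOM      3  C   ALA A   1       0.000   1.000   0.000  0.50 12.00           C
"""


@pytest.fixture
def toy_pdb_text():
    return TOY_PDB


def random_rigid(rng):
    """A uniformly random proper rotation and a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-10, 10, size=3)
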