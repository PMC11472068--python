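import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rnatopo.fixtures import HelixParams, generate_a_form_helix
from rnatopo.structure_model import select_residues


@pytest.fixture(scope="session")
def helix10():
    return generate_a_form_helix(HelixParams(n_bp=10))


@pytest.fixture(scope="session")
def helix10_residues(helix10):
    return select_residues(helix10)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


def random_chain(rng: np.random.Generator, n: int, step: float = 6.0) -> np.ndarray:
    """A random smooth 3D chain with roughly constant step length, emulating
    backbone C3' spacing."""
    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    # smooth the walk so consecutive steps do not fold back onto each other
    for k in range(1, n):
        directions[k] = 0.6 * directions[k - 1] + 0.4 * directions[k]
        directions[k] /= np.linalg.norm(directions[k])
    return np.cumsum(step * directions, axis=0)
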