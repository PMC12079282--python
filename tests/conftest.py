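import numpy as np
import pytest

from catqspr.structures import Atom, Molecule


@pytest.fixture
def h2():
    return Molecule("H2", [Atom("H", [0.0, 0.0, 0.0]),
                           Atom("H", [0.0, 0.0, 0.74])])


@pytest.fixture
def hf():
    return Molecule("HF", [Atom("H", [0.0, 0.0, 0.0]),
                           Atom("F", [0.0, 0.0, 0.92])])


@pytest.fixture
def water():
    # atom order O, H, H
    return Molecule("H2O", [
        Atom("O", [0.0, 0.0, 0.0]),
        Atom("H", [0.9572, 0.0, 0.0]),
        Atom("H", [-0.2399872, 0.9266272, 0.0]),
    ])


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation matrix via QR of a Gaussian."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
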