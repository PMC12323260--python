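import numpy as np
import pytest

from shakediff.chains import build_chain, extended_chain_spec
from shakediff.constraints import ConstraintSet, GeometricConstraint


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def chain6():
    """Extended 6-atom carbon chain."""
    return build_chain(extended_chain_spec(6))


@pytest.fixture
def bond_set6(chain6):
    """Five covalent-bond distance constraints on the 6-atom chain."""
    return ConstraintSet(
        [GeometricConstraint("distance", (i, i + 1), 1.53) for i in range(5)]
    )


def random_se3(rng):
    """Random rotation matrix and translation vector."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(size=3) * 5.0
    return Q, t
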