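import sympy as sp
import pytest

from planarcrn import network_model as nm
from planarcrn import fixtures


@pytest.fixture
def unit_square_cycle():
    return nm.ReactionNetwork(
        [(0, 0), (1, 0), (1, 1), (0, 1)], [(0, 1), (1, 2), (2, 3), (3, 0)]
    )


@pytest.fixture
def quadrangle_31():
    return fixtures.quadrangle_3_1(kappa=(1, 1, 1, 1))


@pytest.fixture
def chain_41():
    return fixtures.chain_4_1_network(sp.Rational(1, 4), sp.Rational(15, 8))


@pytest.fixture
def quadrangle_31_json(tmp_path, quadrangle_31):
    path = tmp_path / "q31.json"
    nm.save_network(quadrangle_31, path)
    return path


# reversible-center (Cor 2) and Lienard-center (Cor 3) instances used by
# several test modules
COR2_INSTANCE = dict(
    p=2, q=1,
    c=(1, sp.Rational(1, 2), -1),
    d=(-1, 1, sp.Rational(-1, 2)),
)

COR3_INSTANCE = dict(
    c=(4, -1, -2),
    d=(-5, 2, 1),
    K=1,
)
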