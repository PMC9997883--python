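import numpy as np
import pytest

from evocpm.lattice import Genotype, PhysicalParams
from evocpm.synthetic import make_toy_lattices


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_lattices():
    return make_toy_lattices()


@pytest.fixture
def small_params():
    """Irregular parameter values so symmetric errors cannot cancel."""
    return PhysicalParams(
        temperature=20.0,
        target_volume=[0, 25, 40],
        lambda_volume=[0, 3, 2],
        target_perimeter=[0, 30, 40],
        lambda_perimeter=[0, 1.5, 2.5],
        adhesion=[[0, 11, 7], [11, 5, 3], [7, 3, 9]],
    )


@pytest.fixture
def free_genotype():
    """The free-environment evolved optimum."""
    return Genotype(max_act=50.0, lambda_act=1165.0)
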