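import numpy as np
import pytest

from selgamd import make_double_well, make_solute_solvent
from selgamd.md_engine import IntegratorConfig
from selgamd.region_decomposition import DecomposedSystem


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def double_well():
    return make_double_well(15.0)


@pytest.fixture
def small_mixture():
    """4-bead solute chain with one torsion plus 12 solvent beads."""
    return make_solute_solvent(4, 12, seed=5)


@pytest.fixture
def small_mixture_model(small_mixture):
    return DecomposedSystem(small_mixture)


def surface_cfg(n_steps, seed=0, stride=5, dt=0.1, friction=2.0, T=300.0):
    return IntegratorConfig(
        timestep=dt, temperature=T, friction=friction,
        n_steps=n_steps, output_stride=stride, seed=seed,
    )


@pytest.fixture
def make_cfg():
    return surface_cfg
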