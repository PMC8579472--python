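import numpy as np
import pytest

from fegrad.alchemy import SamplerConfig
from fegrad.forcefield import ParameterSpace
from fegrad.toysim import Species, ThermoState, ToySystem, build_solvation_box


@pytest.fixture(scope="session")
def tiny_lj_box():
    """Small apolar solvation box for fast sampling tests (21 particles)."""
    solute = Species("solute", sigma=0.47, epsilon=2.0, charge=0.0,
                     role="solute")
    solvent = Species("solvent", sigma=0.42, epsilon=0.8, charge=0.0)
    return build_solvation_box(solute, {solvent: 20}, L=2.2, r_c=0.9,
                               seed=5, tether_k=10.0)


@pytest.fixture(scope="session")
def tiny_space():
    return ParameterSpace.create(
        names=("solute.sigma", "solute.epsilon", "solute.charge"),
        kinds=("sigma", "epsilon", "charge"),
        K0=(0.47, 2.0, 0.0), t=(0.05, 0.5, 0.1),
        frozen=(False, False, True))


@pytest.fixture(scope="session")
def state():
    return ThermoState(T=298.15)


@pytest.fixture
def fast_sampler():
    return SamplerConfig(seed=42, n_equil=1000, n_steps=10000, save_every=50)


@pytest.fixture(scope="session")
def two_particle_system():
    """Two neutral LJ particles at separation sigma in a periodic box."""
    a = Species("a", 0.4, 1.0, 0.0, role="solute")
    b = Species("b", 0.4, 1.0, 0.0)
    pos = np.array([[1.0, 1.0, 1.0], [1.4, 1.0, 1.0]])
    return ToySystem(L=3.0, r_c=1.4, positions=pos,
                     species={"a": a, "b": b}, labels=("a", "b"))
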