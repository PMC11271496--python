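"""Shared fixtures: small water systems, potentials, fast SOAP settings."""

import pytest

from mlal.core import Configuration, ConfigurationSet
from mlal.descriptors import SoapParams
from mlal.dynamics import MDParams, run_md
from mlal.potentials import ToyWaterPotential, TwoBondReactivePotential
from mlal.systems import (
    equilibrated_water_cluster,
    make_reactive_dimer,
    make_water_cluster,
    make_water_molecule,
)


@pytest.fixture(scope="session")
def water_pot():
    return ToyWaterPotential()


@pytest.fixture(scope="session")
def reactive_pot():
    return TwoBondReactivePotential()


@pytest.fixture(scope="session")
def water_molecule():
    return make_water_molecule()


@pytest.fixture(scope="session")
def cluster8(water_pot):
    """Small equilibrated 8-water cluster (24 atoms) for MD/selector tests."""
    return equilibrated_water_cluster(8, water_pot, rng_seed=3, equilibration_fs=300.0)


@pytest.fixture(scope="session")
def raw_cluster8():
    return make_water_cluster(8, rng_seed=3)


@pytest.fixture
def soap_small():
    """Cheap SOAP settings for unit tests."""
    return SoapParams(r_cut=4.0, n_max=3, l_max=2, sigma_atom=0.4, species=("H", "O"))


@pytest.fixture(scope="session")
def thermal_frames8(water_pot, cluster8):
    """Labeled thermal frames of the 8-water cluster from a short reference run."""
    traj = run_md(
        cluster8,
        water_pot,
        MDParams(dt=0.5, temperature=300.0, ensemble="NVT", duration=300.0,
                 rng_seed=5, stride=20),
    )
    frames = [water_pot.label_config(f.stripped()) for f in traj.frames[1:]]
    return ConfigurationSet(frames, name="thermal8")


@pytest.fixture(scope="session")
def reactant_dimer():
    return make_reactive_dimer(3.2, 3.2)
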