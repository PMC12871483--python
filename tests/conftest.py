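import numpy as np
import pytest

import vesiclense as v


@pytest.fixture(scope="session")
def params140():
    """POPC-like membrane at 140 kT, room-temperature D2O."""
    return v.MembraneParams.from_kT(140.0)


@pytest.fixture(scope="session")
def pop60():
    """Typical extruded population: 60 nm mean radius, 25% polydispersity."""
    return v.VesiclePopulation(mean_radius=60e-9, polydispersity=0.25)


@pytest.fixture(scope="session")
def diffusion_se():
    return v.DiffusionSpec()


@pytest.fixture(scope="session")
def grid_standard():
    return v.make_grid("standard")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_membrane(rng):
    """Random valid membrane parameters over the experimentally relevant
    ranges (rigidity 5-1000 kT, tension up to 5 mN/m, membrane viscosity
    up to 1 nPa s m)."""
    return v.MembraneParams.from_kT(
        float(rng.uniform(5.0, 1000.0)),
        temperature=float(rng.uniform(280.0, 330.0)),
        eta_in=float(rng.uniform(0.5e-3, 2e-3)),
        eta_out=float(rng.uniform(0.5e-3, 2e-3)),
        eta_m=float(rng.uniform(0.0, 1e-9)),
        sigma=float(rng.uniform(0.0, 5e-3)),
        delta=float(rng.uniform(3e-9, 5e-9)),
    )
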