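import numpy as np
import pytest

from posaqua.forcefield import embedded_parameters
from posaqua.liquid import LiquidConfiguration


@pytest.fixture(scope="session")
def water_spec():
    return embedded_parameters("water")


@pytest.fixture(scope="session")
def glycine_spec():
    return embedded_parameters("glycine")


def build_configuration(solute_spec, water_positions, box_edge,
                        water_rotations=None):
    """Hand-build a LiquidConfiguration with waters at given O positions."""
    water = embedded_parameters("water")
    n = len(water_positions)
    coords = np.empty((n, 3, 3))
    for i, pos in enumerate(water_positions):
        R = np.eye(3) if water_rotations is None else water_rotations[i]
        coords[i] = water.coords @ R.T + np.asarray(pos, float)
    solute_coords = None
    if solute_spec is not None:
        solute_coords = solute_spec.coords + box_edge / 2.0
    return LiquidConfiguration(solute=solute_spec,
                               solute_coords=solute_coords,
                               water=water, water_coords=coords,
                               box_edge=box_edge)


@pytest.fixture(scope="session")
def small_glycine_box():
    """Deterministic small equilibrated glycine box shared across tests."""
    from posaqua.mc import MCParams, run_npt
    from posaqua.synthetic import FixtureSpec, make_lattice_box

    cfg = make_lattice_box(FixtureSpec(seed=5, n_waters=64,
                                       solute="glycine"))
    params = MCParams(n_steps=60_000, n_equilibration=40_000, seed=9,
                      sample_stride=100, config_stride=2_000)
    return run_npt(cfg, params)
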