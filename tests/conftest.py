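import numpy as np
import pytest

from metastab.synthetic_data import TrajectorySpec, simulate_metastable_trajectory
from metastab.traj_io import Atom, Trajectory


def toy_trajectory(coords_per_frame, atoms):
    """Trajectory from explicit coordinates: list of frames, each a list of xyz."""
    return Trajectory(atoms=atoms, frames=np.asarray(coords_per_frame, dtype=float))


def atom(name="CA", element="C", resid=1, resname="ALA", chain="A", hetero=False):
    return Atom(
        name=name,
        element=element,
        residue_index=resid,
        residue_name=resname,
        chain=chain,
        is_hetero=hetero,
    )


@pytest.fixture(scope="session")
def planted_trajectory():
    """One synthetic ensemble with three planted states (0.6/0.3/0.1)."""
    spec = TrajectorySpec(n_frames=2000, seed=11)
    traj, truth = simulate_metastable_trajectory(spec)
    return spec, traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
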