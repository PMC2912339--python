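import numpy as np
import pytest

from trajscope.model_io import AtomRecord, Selection, Topology, Trajectory
from trajscope.synthetic_data import (
    HingeSpec,
    make_hinge_trajectory,
    make_two_domain_chain,
)


@pytest.fixture(scope="session")
def hinge_spec():
    return HingeSpec(n_fixed=100, n_moving=80, amplitude=25.0,
                     noise_sigma=0.0, n_frames=200, seed=7)


@pytest.fixture(scope="session")
def hinge_fixture(hinge_spec):
    """Noise-free planted 25° hinge trajectory with its manifest."""
    top, ref = make_two_domain_chain(hinge_spec)
    traj, manifest = make_hinge_trajectory(top, ref, hinge_spec)
    return top, ref, traj, manifest


def toy_topology(n, name="CA", resname="GLY", **extra):
    atoms = [
        AtomRecord(serial=i + 1, name=name, residue_name=resname,
                   residue_id=i + 1, **extra)
        for i in range(n)
    ]
    return Topology(atoms)


def static_trajectory(coords, n_frames=5):
    coords = np.asarray(coords, float)
    top = toy_topology(coords.shape[0])
    return Trajectory(top, np.repeat(coords[None], n_frames, axis=0))


def full_selection(n):
    return Selection(tuple(range(n)))
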