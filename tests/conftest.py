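import numpy as np
import pytest

from vardyn import synthdyn
from vardyn.trajio import Atom, Topology, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tripeptide_topology():
    """Three-residue backbone-only topology (N, CA, C, O per residue)."""
    atoms = []
    for resid in (1, 2, 3):
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(Atom(name, elem, resid, "ALA", "A"))
    return Topology(atoms)


@pytest.fixture
def small_gaussian_traj(rng):
    """A 5-atom, 50-frame isotropic Gaussian ensemble."""
    ref = rng.uniform(-5.0, 5.0, (5, 3))
    spec = synthdyn.EnsembleSpec(ref, 0.09 * np.eye(15), n_frames=50, seed=7)
    return synthdyn.gen_gaussian_ensemble(spec)


def random_rotation(rng) -> np.ndarray:
    """A uniform random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def rigid_copy(traj: Trajectory, rot: np.ndarray, shift: np.ndarray) -> Trajectory:
    return Trajectory(traj.topology, traj.coords @ rot.T + shift, traj.times.copy())
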