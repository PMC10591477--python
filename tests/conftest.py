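import numpy as np
import pytest

from tndyn import synthetic
from tndyn.structure_io import AtomRecord, Topology, Trajectory


@pytest.fixture(scope="session")
def small_system():
    """2 runs x 100 frames of the default wild-type-like synthetic system."""
    spec = synthetic.SyntheticSpec(n_runs=2, frames_per_run=100, seed=42)
    traj, truth = synthetic.generate_trajectory(spec)
    return traj, truth


@pytest.fixture(scope="session")
def toy_topology():
    return synthetic.build_toy_topology(synthetic.SyntheticSpec())


def make_point_topology(points: dict[str, list]) -> tuple[Topology, np.ndarray]:
    """Topology of bare CA atoms: subunit -> list of coordinates.

    Residues are numbered 1..n within each subunit.
    """
    atoms, coords = [], []
    for su, pts in points.items():
        for r, p in enumerate(pts, start=1):
            atoms.append(AtomRecord("CA", "C", su, r, "GLY", len(atoms)))
            coords.append(np.asarray(p, dtype=float))
    return Topology(atoms), np.array(coords)


def make_trajectory(topology: Topology, frames: np.ndarray, run_ids=None) -> Trajectory:
    frames = np.asarray(frames, dtype=float)
    if run_ids is None:
        run_ids = np.zeros(len(frames), dtype=int)
    return Trajectory(topology, frames, np.asarray(run_ids))


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random rotation (QR-based) plus a random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    return Q, t
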