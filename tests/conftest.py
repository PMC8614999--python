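import numpy as np
import pytest

from bindkit.datatypes import HingeSpec, PlantedPoseSpec
from bindkit.synthetic_data import (
    default_ligand_template,
    gen_hinge_trajectory,
    gen_pose_ensemble,
)


@pytest.fixture(scope="session")
def two_cluster_spec():
    """Two pose clusters 10 A apart with the better-scoring cluster first."""
    return PlantedPoseSpec(
        centers=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]),
        spread=[0.5, 0.5],
        counts=[120, 80],
        ligand_template=default_ligand_template(),
        score_model=[(-8.0, 0.5), (-6.0, 0.5)],
    )


@pytest.fixture(scope="session")
def two_cluster_ensemble(two_cluster_spec):
    return gen_pose_ensemble(two_cluster_spec, seed=1)


@pytest.fixture(scope="session")
def hinge_traj():
    """Closing trajectory, 15 -> 4 A, light jitter."""
    return gen_hinge_trajectory(
        HingeSpec(n_frames=40, start_gap=15.0, end_gap=4.0, jitter_sd=0.1), seed=2
    )


@pytest.fixture(scope="session")
def hinge_traj_clean():
    """Jitter-free closing trajectory (exact planted geometry)."""
    return gen_hinge_trajectory(
        HingeSpec(n_frames=40, start_gap=15.0, end_gap=4.0, jitter_sd=0.0), seed=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def chain_indices(traj, chain):
    return np.nonzero(traj.topology.chain == chain)[0]
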