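import numpy as np
import pytest

from hipfe.cohort import CohortConfig, generate_cohort_table
from hipfe.fe import FEModel, _NODE_OFFSETS
from hipfe.phantom import PhantomConfig, generate_phantom


def make_column_model(nx=2, ny=2, nz=6, h=3.0, e=5000.0, sigy=35.0,
                      target=None):
    """Homogeneous cuboid column compressed along z with lateral-free ends.

    The uniform uniaxial state is exactly representable by trilinear hexes,
    so the elastic reaction is E*A*u/L and the plastic plateau sigma_y*A.
    """
    node_shape = (nx + 1, ny + 1, nz + 1)

    def nid(i, j, k):
        return (i * node_shape[1] + j) * node_shape[2] + k

    nodes = np.array([(i * h, j * h, k * h)
                      for i in range(node_shape[0])
                      for j in range(node_shape[1])
                      for k in range(node_shape[2])], float)
    els = np.array([[nid(i + o[0], j + o[1], k + o[2]) for o in _NODE_OFFSETS]
                    for i in range(nx) for j in range(ny) for k in range(nz)])
    nel = len(els)
    top = np.where(np.isclose(nodes[:, 2], nz * h))[0]
    bot = np.where(np.isclose(nodes[:, 2], 0))[0]
    if target is None:
        target = 0.02 * nz * h
    pinned = ((int(nid(0, 0, 0)), 0), (int(nid(0, 0, 0)), 1),
              (int(nid(nx, 0, 0)), 1))
    return FEModel(nodes=nodes, elements=els, e_modulus=np.full(nel, e),
                   yield_stress=np.full(nel, sigy),
                   is_padding=np.zeros(nel, bool), h=h,
                   fixed_nodes=np.empty(0, np.int64), driven_nodes=top,
                   load_case="stance", target_displacement=target,
                   fixed_z_nodes=bot, pinned=pinned)


@pytest.fixture
def column_model():
    return make_column_model


@pytest.fixture(scope="session")
def default_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def mini_config():
    """A ~2/3-scale femur geometry for fast whole-bone FE tests."""
    return PhantomConfig(
        head_radius=15.5, neck_radius_base=11.0, neck_radius_head=9.5,
        neck_base_z=30.0, neck_length=34.0, shaft_radius=10.0,
        shaft_top_z=34.0, troch_center=(-5.0, 0.0, 39.0),
        troch_semiaxes=(10.0, 9.0, 11.5), cth_shaft=2.6, cth_troch=2.1)


@pytest.fixture(scope="session")
def mean_phantom(default_config):
    """Population-mean phantom (latent quality 0), shared across tests."""
    return generate_phantom(default_config, 0.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-subject cohort table for fast statistical tests."""
    return generate_cohort_table(CohortConfig(n_subjects=300, seed=11))


@pytest.fixture(scope="session")
def study_cohort():
    """A full-size (n = 740) cohort table."""
    return generate_cohort_table(CohortConfig(n_subjects=740, seed=5))
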