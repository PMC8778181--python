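import numpy as np
import pytest

from facelattice.face_tree import N_NODES, TrivialTree
from facelattice.lattice_metric import IntervalTree, MetricParams
from facelattice.synthetic_data import pose_trees


def random_trivial_tree(rng) -> TrivialTree:
    return TrivialTree(
        r=rng.uniform(0.0, 2.0, N_NODES),
        phi=rng.uniform(-np.pi, np.pi, N_NODES),
    )


def random_interval_tree(rng) -> IntervalTree:
    r_lo = rng.uniform(0.0, 2.0, N_NODES)
    phi_lo = rng.uniform(-np.pi, np.pi - 0.5, N_NODES)
    return IntervalTree(
        r_lo=r_lo,
        r_hi=r_lo + rng.uniform(0.0, 0.5, N_NODES),
        phi_lo=phi_lo,
        phi_hi=phi_lo + rng.uniform(0.0, 0.5, N_NODES),
    )


def random_params(rng) -> MetricParams:
    return MetricParams(
        lambda_r=rng.uniform(0.0, 10.0, N_NODES),
        lambda_phi=rng.uniform(0.0, 10.0, N_NODES),
        k_r123=rng.uniform(0.0, 10.0, 3),
        k_phi123=rng.uniform(0.0, 10.0, 3),
        k_r=float(rng.uniform(0.0, 10.0)),
        k_phi=float(rng.uniform(0.0, 10.0)),
    )


def flat_l1_oracle(ta, tb, params: MetricParams) -> float:
    """Independent closed-form oracle: weighted L1 over all 59 nodes and
    both coordinates, with hierarchy weights written out by hand."""
    from facelattice.lattice_metric import as_interval

    ta, tb = as_interval(ta), as_interval(tb)

    def hierarchy_weights(k3):
        w = np.ones(59)
        w[8:19] = k3[0]   # secondaries under the left-eye primary (ids 9-19)
        w[19:30] = k3[1]  # under the right-eye primary (ids 20-30)
        w[30:59] = k3[2]  # under the mouth primary (ids 31-59)
        return w

    d_r = np.sum(
        hierarchy_weights(params.k_r123)
        * params.lambda_r
        * (np.abs(ta.r_lo - tb.r_lo) + np.abs(ta.r_hi - tb.r_hi))
    )
    d_phi = np.sum(
        hierarchy_weights(params.k_phi123)
        * params.lambda_phi
        * (np.abs(ta.phi_lo - tb.phi_lo) + np.abs(ta.phi_hi - tb.phi_hi))
    )
    return params.k_r * d_r + params.k_phi * d_phi


@pytest.fixture(scope="session")
def low_noise_pose_data():
    """Labeled trees for all 11 sub-classes at the easiest noise preset."""
    return pose_trees(20, "40cm_normal", seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
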