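import numpy as np
import pytest

from tractnet import (
    BundleSpec,
    ConnectivityNetwork,
    GroupDesign,
    generate_group_connectomes,
    generate_tensor_phantom,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study design (6 vs 6, 150 nodes)."""
    return generate_group_connectomes(GroupDesign(seed=12345))


@pytest.fixture(scope="session")
def small_design():
    """A scaled-down design for fast end-to-end tests."""
    return GroupDesign(n_per_group=4, n_nodes=60, n_modules=4, seed=7)


@pytest.fixture(scope="session")
def straight_phantom():
    """Straight-bundle tensor phantom along x with labeled end-caps."""
    vs = 0.08
    shape = (40, 11, 11)
    y = shape[1] * vs / 2
    z = shape[2] * vs / 2
    bundle = BundleSpec(
        points=((3 * vs, y, z), ((shape[0] - 3) * vs, y, z)),
        radius=1.6 * vs,
        cap_length=3 * vs,
    )
    field, md_map, parc = generate_tensor_phantom(
        shape, [bundle], fa_inside=0.8, voxel_size=vs
    )
    return field, md_map, parc, bundle


def random_weighted_graph(n, p, rng, connected=True):
    """Random symmetric weighted test graph (helper, not a fixture)."""
    while True:
        W = np.triu((rng.random((n, n)) + 0.1) * (rng.random((n, n)) < p), 1)
        W += W.T
        if not connected:
            return W
        # simple connectivity check via matrix powers of the support
        A = (W > 0).astype(float) + np.eye(n)
        reach = np.linalg.matrix_power(A, n) > 0
        if reach.all():
            return W


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
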