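from pathlib import Path

import numpy as np
import pytest

import qdabiplot as q

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def three_group_data():
    """Seeded 150 x 4 three-group Gaussian fixture (50 per group).

    Seed 1 matches the bundled fixture pair in tests/data/.
    """
    return q.simulate_normal(q.three_group_spec(seed=1))


@pytest.fixture(scope="session")
def three_group_model(three_group_data):
    model = q.fit_quadratic(three_group_data, priors="proportional")
    return q.build_phi_matrix(three_group_data, model)


@pytest.fixture(scope="session")
def three_group_layout(three_group_model):
    return q.qda_scores(three_group_model, r=2)


@pytest.fixture(scope="session")
def two_group_data():
    """Seeded two-group 200 x 4 Gaussian fixture with unequal covariances."""
    spec = q.SimulationSpec(
        group_means=[[0.0, 0.0, 0.0, 0.0], [1.0, 1.5, -1.0, 0.5]],
        group_covs=[np.eye(4), 2.5 * np.eye(4)],
        sizes=[100, 100],
        seed=11,
    )
    return q.simulate_normal(spec)


@pytest.fixture(scope="session")
def two_group_binary_data():
    """Seeded two-group binary presence/absence fixture (200 x 4)."""
    return q.pathogen_panel(
        n_per_group=100,
        p=4,
        presence_probs=[[0.2, 0.3, 0.6, 0.7], [0.7, 0.6, 0.3, 0.2]],
        seed=13,
    )
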