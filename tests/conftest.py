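import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def table1_q():
    from pgdina import study_q_matrix

    return study_q_matrix()


@pytest.fixture(scope="session")
def small_q():
    """10-item, 2-attribute Q-matrix satisfying the Gu-Xu conditions."""
    import numpy as np

    from pgdina import QMatrix

    rows = [[1, 0], [0, 1], [1, 0], [0, 1], [1, 1],
            [1, 1], [1, 0], [0, 1], [1, 1], [1, 1]]
    return QMatrix(np.array(rows))


@pytest.fixture(scope="session")
def lnl_dataset(table1_q):
    """One LNL replicate (N=1000) shared by the heavier estimation tests."""
    import numpy as np

    from pgdina import SimulationCondition, generate_dataset

    cond = SimulationCondition(N=1000, Q=table1_q, noise="LNL")
    return generate_dataset(cond, np.random.default_rng(42))
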