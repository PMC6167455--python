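import numpy as np
import pytest

from assocfractal import SemanticSpace, gen_space


@pytest.fixture
def axis_space() -> SemanticSpace:
    """Tiny hand-written space with known geometry.

    hund/katze are identical directions, nord is orthogonal to hund,
    diag sits at 45 degrees between them.
    """
    return SemanticSpace(
        ["hund", "katze", "nord", "diag"],
        np.array(
            [
                [1.0, 0.0],
                [2.0, 0.0],
                [0.0, 1.0],
                [1.0, 1.0],
            ]
        ),
    )


@pytest.fixture(scope="session")
def small_space() -> SemanticSpace:
    """A modest clustered random space shared across tests."""
    return gen_space(
        vocab_size=500, dim=12, n_clusters=10, within_cluster_cosine=0.6, seed=7
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
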