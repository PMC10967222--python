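import numpy as np
import pytest
from hypothesis import settings

from crossimpact import CrossImpactMatrix, GoalSet

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def abc_goals():
    return GoalSet(["A", "B", "C"])


@pytest.fixture
def abc_matrix(abc_goals):
    # rows influence columns: A->B=1, A->C=2, B->C=3, C->A=-1
    return CrossImpactMatrix(abc_goals, [[0, 1, 2], [0, 0, 3], [-1, 0, 0]])


@pytest.fixture
def sdg16():
    return GoalSet.sdg_default(16)


@pytest.fixture
def zero16(sdg16):
    return CrossImpactMatrix(sdg16, np.zeros((16, 16), dtype=int))


@pytest.fixture
def plus3_16(sdg16):
    w = np.full((16, 16), 3, dtype=int)
    np.fill_diagonal(w, 0)
    return CrossImpactMatrix(sdg16, w)


def random_matrix(n_goals: int, rng: np.random.Generator) -> CrossImpactMatrix:
    """Uniform random integer matrix in [-3, 3] with zero diagonal."""
    w = rng.integers(-3, 4, size=(n_goals, n_goals))
    np.fill_diagonal(w, 0)
    return CrossImpactMatrix(GoalSet([f"G{i}" for i in range(n_goals)]), w)
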