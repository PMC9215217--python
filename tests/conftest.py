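import numpy as np
import pytest

from oceanot import DepthAxis, GridSpec, ProbabilityField, ScalarField


@pytest.fixture
def small_grid() -> GridSpec:
    """A 4x5 all-ocean grid in the central Pacific."""
    return GridSpec.regular(-160.0, -140.0, 0.0, 15.0, 5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture
def depth_axis() -> DepthAxis:
    return DepthAxis(np.arange(0.0, 201.0, 4.0))


def random_map_pair(grid: GridSpec, rng: np.random.Generator):
    """Two random probability fields on the full valid support of a grid."""
    fields = []
    for _ in range(2):
        from oceanot import normalize_field

        vals = rng.uniform(0.05, 1.0, grid.shape)
        fields.append(normalize_field(ScalarField(grid, vals)))
    return fields


def random_profile(rng: np.random.Generator, n_max: int = 40) -> ProbabilityField:
    n = int(rng.integers(2, n_max + 1))
    depths = np.sort(rng.choice(np.arange(0.0, 200.0, 0.5), size=n, replace=False))
    return ProbabilityField(rng.dirichlet(np.ones(n)), axis=DepthAxis(depths))
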