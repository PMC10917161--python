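import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netpyramid.atlas import AtlasHierarchy, load_default_hierarchy

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gm_hierarchy() -> AtlasHierarchy:
    """The packaged five-scale gray-matter hierarchy (84/58/16/6/4)."""
    return load_default_hierarchy()


def make_toy_hierarchy(n_parcels: int = 12, per_module: int = 3) -> AtlasHierarchy:
    """Compact 3-scale tree: n_parcels -> n_parcels/per_module modules -> 2 halves."""
    n_modules = n_parcels // per_module
    parcels1 = tuple((i, f"p{i:02d}") for i in range(1, n_parcels + 1))
    parcels2 = tuple((i, f"m{i}") for i in range(1, n_modules + 1))
    parcels3 = tuple((i, f"h{i}") for i in range(1, 3))
    parent1 = {i: i for i in range(1, n_parcels + 1)}
    parent2 = {i: (i - 1) // per_module + 1 for i in range(1, n_parcels + 1)}
    parent3 = {i: (i - 1) // (n_parcels // 2) + 1 for i in range(1, n_parcels + 1)}
    return AtlasHierarchy(parcels=(parcels1, parcels2, parcels3),
                          parent=(parent1, parent2, parent3))


@pytest.fixture(scope="session")
def toy_hierarchy() -> AtlasHierarchy:
    """12 parcels -> 4 modules -> 2 halves."""
    return make_toy_hierarchy(12, 3)


@pytest.fixture(scope="session")
def toy16_hierarchy() -> AtlasHierarchy:
    """16 parcels -> 4 modules -> 2 halves; used for cohort simulations."""
    return make_toy_hierarchy(16, 4)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
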