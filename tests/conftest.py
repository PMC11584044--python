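import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import leafmorph as lm
from leafmorph.landmarking import landmark_outline

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def simple_leaf():
    """One deterministic noise-free leaf."""
    return lm.generate_leaf(
        lm.LeafParams(lobe_count=4, lobe_depth=0.4, elongation=2.5, asymmetry_sd=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def leaf_set():
    """A small varied set of noise-free leaves with their configurations."""
    leaves = [
        lm.generate_leaf(
            lm.LeafParams(
                lobe_count=c, lobe_depth=d, elongation=e, asymmetry_sd=0.0, seed=i
            ),
            id=f"leaf{i}",
        )
        for i, (c, d, e) in enumerate(
            [(0, 0.0, 2.0), (2, 0.3, 2.5), (4, 0.5, 3.0), (5, 0.7, 2.2), (7, 0.85, 3.5),
             (3, 0.2, 1.8), (6, 0.6, 4.0), (1, 0.1, 2.8)]
        )
    ]
    configs = [landmark_outline(leaf, S=50) for leaf in leaves]
    return leaves, configs


@pytest.fixture(scope="session")
def archetype_sets():
    return lm.generate_archetypes(S=50)


def unit_square(trace_from=0):
    """Unit-square outline traced from a chosen corner."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    pts = np.roll(pts, -trace_from, axis=0)
    return lm.LeafOutline(id="square", points=pts)
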