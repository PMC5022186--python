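import numpy as np
import pytest

from psmvc import LatentFactors, ProteinUniverse, WeightedNetworkView


def make_random_view(
    rng: np.random.Generator,
    universe: ProteinUniverse,
    density: float = 0.5,
    coverage: float = 1.0,
) -> WeightedNetworkView:
    """Random symmetric nonnegative score matrix with a coverage mask."""
    n = len(universe)
    upper = rng.uniform(size=(n, n)) * (rng.uniform(size=(n, n)) < density)
    W = np.triu(upper, 1)
    W = W + W.T
    theta = np.zeros(n)
    n_cov = max(1, int(round(coverage * n)))
    theta[rng.choice(n, size=n_cov, replace=False)] = 1.0
    W *= np.outer(theta, theta)
    return WeightedNetworkView(universe, W, theta)


def make_random_factors(
    rng: np.random.Generator, n: int, k_c: int, k_s: int
) -> LatentFactors:
    return LatentFactors(
        rng.uniform(size=(n, k_c)),
        (rng.uniform(size=(n, k_s)), rng.uniform(size=(n, k_s))),
    )


def raw_view(universe, W, theta) -> WeightedNetworkView:
    """Build a view without invariant validation (for oracle tests that
    need e.g. a nonzero diagonal or off-mask scores)."""
    v = WeightedNetworkView.__new__(WeightedNetworkView)
    v.universe, v.W, v.theta = universe, np.asarray(W, float), np.asarray(theta, float)
    return v


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_universe() -> ProteinUniverse:
    return ProteinUniverse([f"P{i}" for i in range(6)])
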