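import numpy as np
import pytest

from patchconn import generate_connectivity_cohort


@pytest.fixture(scope="session")
def effect_cohort():
    """30-node, 20+20 cohort with a strong effect at nodes {3, 7, 11}."""
    return generate_connectivity_cohort(
        30, {"control": 20, "case": 20},
        affected_nodes={3, 7, 11}, effect_size=0.9, seed=11,
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Exchangeable 30-node, 20+20 cohort (no effect)."""
    return generate_connectivity_cohort(
        30, {"control": 20, "case": 20}, effect_size=0.0, seed=12,
    )


@pytest.fixture(scope="session")
def random_connectomes():
    """A small stack of valid random connectivity matrices (no group structure)."""
    rng = np.random.default_rng(5)
    n, N = 12, 15
    stack = np.empty((n, N, N))
    for u in range(n):
        X = rng.standard_normal((N, 40))
        stack[u] = np.corrcoef(X)
        np.fill_diagonal(stack[u], 1.0)
    return stack
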