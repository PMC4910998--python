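import numpy as np
import pytest

from miscan import simdata


@pytest.fixture(scope="session")
def small_sim():
    """Mixed-quality cohort: 300 samples x 150 variants, no causal signal."""
    return simdata.simulate(
        simdata.SimConfig(n_samples=300, n_variants=150, seed=11)
    )


@pytest.fixture(scope="session")
def causal_sim():
    """Cohort with a sprinkling of causal variants for signal-bearing tests."""
    return simdata.simulate(
        simdata.SimConfig(
            n_samples=400, n_variants=200, causal_fraction=0.1,
            causal_beta=0.4, seed=17,
        )
    )


@pytest.fixture(scope="session")
def degenerate_sim():
    """Perfect-confidence cohort (target quality 1 => triples are truth)."""
    return simdata.simulate(
        simdata.SimConfig(
            n_samples=120, n_variants=40, quality_dist=("fixed", 1.0),
            causal_fraction=0.1, causal_beta=0.5, seed=23,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
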