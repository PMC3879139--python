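import numpy as np
import pytest

import popmaxent as pm
from popmaxent.stats import EmpiricalStats


def stats_from_exact(dist, T=283041):
    """EmpiricalStats carrying a model's exact moments (binomial-fallback
    errors apply at sample size T)."""
    n = dist.n_neurons
    return EmpiricalStats(
        dist.rates, dist.moments, np.zeros((n, n)), dist.p_k,
        np.zeros(n), np.zeros((n, n)), np.zeros((n, n)), np.zeros(n + 1), T)


@pytest.fixture(scope="session")
def indep_model():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.02, 0.2, 8)
    return pm.MaxEntModel("independent", np.log(p / (1 - p))), p


@pytest.fixture(scope="session")
def pairwise_gen():
    spec = pm.GeneratorSpec(n_neurons=6, j_scale=0.5, seed=11)
    return pm.make_ground_truth_model(spec)


@pytest.fixture(scope="session")
def kpair_gen():
    spec = pm.GeneratorSpec(n_neurons=8, j_scale=0.4, v_scale=1.0, seed=12)
    return pm.make_ground_truth_model(spec)


@pytest.fixture(scope="session")
def small_raster():
    """Deterministic 4-neuron raster with repeat structure."""
    rng = np.random.default_rng(42)
    values = (rng.random((4, 60)) < 0.25).astype(np.uint8)
    return pm.SpikeRaster(values, n_repeats=5, bins_per_repeat=12, dt=0.02)
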