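import numpy as np
import pytest

from latency_readout import retina
from latency_readout.spikeio import SpikeTrain, TrialPattern
from latency_readout.tempotron import PSPKernel, TempotronModel


@pytest.fixture
def kernel():
    return PSPKernel(tau_m=10.0, tau_s=2.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_pattern(rng, n_aff=5, max_spikes=4, window=150.0):
    trains = []
    for i in range(n_aff):
        n = int(rng.integers(0, max_spikes + 1))
        times = tuple(np.sort(rng.uniform(0.0, window, n)))
        trains.append(SpikeTrain(i, tuple(float(t) for t in times)))
    return TrialPattern(0, tuple(trains))


def random_model(rng, n_aff=5, kernel=None):
    return TempotronModel(rng.normal(0.0, 1.0, n_aff), kernel=kernel or PSPKernel())


def grid_peak_oracle(pattern, model, dt=0.01, t_end=None):
    """Independent peak finder: dense grid scan plus bounded local
    refinement of the grid argmax (golden-section via scipy)."""
    from scipy.optimize import minimize_scalar

    from latency_readout.tempotron import voltage_trace

    if t_end is None:
        t_end = 150.0 + 5.0 * model.kernel.tau_m
    grid = np.arange(0.0, t_end, dt)
    v = voltage_trace(pattern, model, grid)
    i = int(np.argmax(v))
    if v[i] <= 0:
        return 0.0, None
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda t: -voltage_trace(pattern, model, np.array([t]))[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(-res.fun), float(res.x)


@pytest.fixture(scope="session")
def grating_population():
    """Small deterministic-seed grating population shared across tests."""
    config = retina.PopulationConfig(n_cells=8, seed=42)
    return retina.sample_population(config), config


@pytest.fixture(scope="session")
def grating_dataset(grating_population):
    pop, config = grating_population
    return retina.simulate_dataset(pop, config, trials_per_condition=15)
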