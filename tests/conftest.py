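import numpy as np
import pytest

import stockhab as sh

QUARTERLY_DATES = tuple(2018.0 + 0.25 * i for i in range(8))

TRUE_LINF = 434.0
TRUE_K = 0.43
TRUE_Z = 1.87


@pytest.fixture(scope="session")
def clean_scenario():
    """Zero-noise population: quarterly samples, 500 fish each, 2 years."""
    return sh.PopulationScenario(
        sample_dates=QUARTERLY_DATES, n_per_sample=500, cv_length=0.0, seed=3
    )


@pytest.fixture(scope="session")
def clean_samples(clean_scenario):
    return sh.simulate_length_frequencies(clean_scenario)


@pytest.fixture(scope="session")
def clean_lfq(clean_samples):
    return clean_samples.to_lfq(10.0)


@pytest.fixture(scope="session")
def clean_restructured(clean_lfq):
    return sh.restructure(clean_lfq, 5)


@pytest.fixture(scope="session")
def noisy_samples():
    scen = sh.PopulationScenario(n_per_sample=300, cv_length=0.08, seed=17)
    return sh.simulate_length_frequencies(scen)


@pytest.fixture(scope="session")
def small_noiseless_grid():
    """Zero-noise habitat world whose true HSI is the AM of depth+SST Gaussians."""
    scen = sh.HabitatScenario(catch_noise_cv=0.0, seed=5)
    return sh.simulate_environment_and_catch(scen)


@pytest.fixture(scope="session")
def search_bounds(clean_samples):
    from stockhab.growth import default_search_bounds

    top = max(v.max() for v in clean_samples.samples.values())
    return default_search_bounds(top)


def random_lfq(rng, n_bins=None, n_samples=None):
    """A small random length-frequency object for property tests."""
    n_bins = n_bins or int(rng.integers(5, 11))
    n_samples = n_samples or int(rng.integers(1, 5))
    counts = rng.integers(0, 30, size=(n_bins, n_samples))
    counts[rng.random(counts.shape) < 0.3] = 0
    dates = 2018.0 + np.sort(rng.choice(np.arange(1, 40), n_samples, replace=False)) / 12.0
    return sh.LengthFrequencyData(50.0 + 10.0 * np.arange(n_bins), dates, counts)
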