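import numpy as np
import pandas as pd
import pytest

from metgei import SimulationConfig, adjusted_means, simulate_met

BASE_SEED = 20180701  # package-wide default seed for deterministic suites

SMALL_TRIALS = [("A", 2018), ("A", 2019), ("B", 2018), ("B", 2019), ("C", 2019)]


def small_config(**kw):
    """10 genotypes x 5 environments, quick enough for per-test fits."""
    defaults = dict(
        n_genotypes=10,
        trials=SMALL_TRIALS,
        missing_trials=[],
        n_two_rep_trials=2,
        seed=BASE_SEED,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def study_sim():
    """One study-scale dataset: 36 genotypes, 17 environments, reps 3/2."""
    return simulate_met(SimulationConfig(seed=BASE_SEED))


@pytest.fixture(scope="session")
def study_table(study_sim):
    data, _ = study_sim
    return adjusted_means(data, "FYLD")


@pytest.fixture(scope="session")
def small_sim():
    return simulate_met(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(BASE_SEED)


def make_table(values, genotypes=None, environments=None):
    """Quick TwoWayMeans from a 2-D array."""
    from metgei import TwoWayMeans

    values = np.asarray(values, float)
    g = genotypes or [f"g{i+1}" for i in range(values.shape[0])]
    e = environments or [f"e{j+1}" for j in range(values.shape[1])]
    return TwoWayMeans(pd.DataFrame(values, index=g, columns=e))
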