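import numpy as np
import pytest

from mucosim import (default_discretization, default_params, run_cohort,
                     sample_cases, simulate, train_metric_maps)
from mucosim.config import load_config
from mucosim.params import Discretization, make_output_times


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def disc():
    return default_discretization()


@pytest.fixture(scope="session")
def coarse_disc():
    """Cheap solver settings for tests that only need qualitative fields."""
    return Discretization(dx_gel=20.0, dx_epi=10.0, dx_stroma=20.0,
                          dt=0.02, t_end=48.0,
                          output_times=make_output_times(48.0, 0.2))


@pytest.fixture(scope="session")
def standard_result(params, disc):
    """One full-resolution run at the standard parameter values."""
    return simulate(params, disc)


@pytest.fixture(scope="session")
def run_config():
    return load_config()


@pytest.fixture(scope="session")
def cohort125(run_config):
    """The full 125-case canonical cohort (shared; ~2 min)."""
    return run_cohort(run_config.grid, run_config.transport, run_config.disc)


@pytest.fixture(scope="session")
def test_cohort(run_config):
    """Independently sampled 40-case test cohort (shared; ~30 s)."""
    return sample_cases(run_config.n_test_cases, run_config.seed,
                        run_config.grid, run_config.transport,
                        run_config.disc)


@pytest.fixture(scope="session")
def trained_maps(run_config, cohort125, test_cohort):
    """Six trained blood-to-stroma metric maps at the default settings."""
    from dataclasses import replace
    nn_cfg = replace(run_config.nn, seed=run_config.seed)
    return train_metric_maps(cohort125, nn_cfg, test_dataset=test_cohort)


@pytest.fixture(scope="session")
def cohort_csv(tmp_path_factory, cohort125):
    path = tmp_path_factory.mktemp("data") / "cohort.csv"
    cohort125.to_csv(path)
    return path


@pytest.fixture(scope="session")
def test_cohort_csv(tmp_path_factory, test_cohort):
    path = tmp_path_factory.mktemp("data") / "test_cohort.csv"
    test_cohort.to_csv(path)
    return path
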