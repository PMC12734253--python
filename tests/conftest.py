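import numpy as np
import pytest

from escalearn.inference import SamplerConfig, run_all_models
from escalearn.inversion import FitConfig, PriorSpec, fit_cohort, fits_to_frame
from escalearn.task import CohortConfig, TaskConfig, accuracy_by_type, simulate_cohort
from escalearn.trajectories import extract_trajectories


@pytest.fixture(scope="session")
def default_params_kwargs():
    return dict(omega2=-3.0, omega3=-6.0, beta=1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """8-subject cohort used by fast unit tests."""
    return simulate_cohort(TaskConfig(seed=11), CohortConfig(n_si=4, n_ctrl=4, seed=11))


@pytest.fixture(scope="session")
def small_fits(small_cohort):
    priors = PriorSpec()
    fits = fit_cohort(small_cohort, priors, FitConfig(n_restarts=1, seed=5))
    return fits, priors


@pytest.fixture(scope="session")
def default_cohort_run():
    """Full default cohort pipeline: simulate -> fit -> extract -> 11 models.

    Shared by the acceptance tests; uses the production sampler settings
    (4 chains, 1000 warmup, 4000 retained draws per chain).
    """
    task, cohort = TaskConfig(seed=0), CohortConfig(seed=0)
    data = simulate_cohort(task, cohort)
    priors = PriorSpec()
    fits = fit_cohort(data, priors, FitConfig(seed=0))
    params = fits_to_frame(fits)
    long_table = extract_trajectories(fits, data, priors)
    summary = run_all_models(
        long_table, params[params["status"] != "all-restarts-failed"], SamplerConfig(seed=0)
    )
    return {
        "data": data,
        "accuracy": accuracy_by_type(data),
        "fits": fits,
        "params": params,
        "long": long_table,
        "summary": summary,
    }
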