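import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import specphyto as sp
from specphyto.pipeline import derive_all_params, sigma_table

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

ZERO_NOISE = {"rlc": 0.0, "induction": 0.0, "light": 0.0}


@pytest.fixture(scope="session")
def zero_noise_campaign():
    """Noise-free 5-station campaign across all five wavelengths."""
    truth = sp.generate_truth(11, n_stations=5, noise_sd=ZERO_NOISE)
    return sp.simulate_campaign(truth=truth)


@pytest.fixture(scope="session")
def zero_noise_params(zero_noise_campaign):
    """Derived parameter table for the noise-free campaign."""
    bundle = zero_noise_campaign
    sigmas = sigma_table(bundle.inductions)
    params = derive_all_params(bundle.rlcs, sigmas)
    return params


@pytest.fixture(scope="session")
def small_noisy_run(tmp_path_factory):
    """A full default-noise pipeline run on a 6-station campaign."""
    cfg = sp.PipelineConfig(seed=7, n_stations=6)
    return sp.run_pipeline(cfg)


def make_detrended_long(rng, stations=4, wavelengths=(440, 480),
                        parameters=("p1", "p2")):
    """Random detrended long table for K-table tests."""
    rows = []
    for st in range(stations):
        for wl in wavelengths:
            for par in parameters:
                rows.append((f"S{st}", wl, par, rng.normal()))
    return pd.DataFrame(rows, columns=["station", "wavelength", "parameter",
                                       "detrended"])
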