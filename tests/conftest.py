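import dataclasses

import numpy as np
import pytest

import ssie
from ssie.fit import SSiEModel
from ssie.lir import LIRSpec
from ssie.synth import generate_ssie_series


@pytest.fixture(scope="session")
def daily_dataset():
    """A 54-day greenhouse-like synthetic series (arrays e, w)."""
    records = ssie.default_dataset(seed=101)
    e = np.array([r.e_avg for r in records])
    w = np.array([r.w_c for r in records])
    return e, w


@pytest.fixture(scope="session")
def cycle_radiation():
    """200 development cycles of aggregated radiation from synthetic weather."""
    weather = ssie.generate_weather(
        dataclasses.replace(ssie.WeatherConfig(), n_days=400, seed=707)
    )
    cycles = ssie.aggregate_to_cycles(weather, 2)
    return np.array([c.e_cd for c in cycles])


def make_ssie_dataset(family, params, e, seed, sigma=0.05, c0=0.0):
    """Sequentially generated SSiE consumption over a radiation series."""
    model = SSiEModel(
        theta1=params["theta1"],
        lir=LIRSpec(family, {k: v for k, v in params.items() if k != "theta1"}),
        sigma=sigma if sigma > 0 else 1e-300,  # ~noiseless but valid model
        sw_offset=c0,
    )
    return generate_ssie_series(e, model, np.random.default_rng(seed))
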