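"""Shared fixtures: every dataset is generated, nothing is stored."""

import dataclasses

import numpy as np
import pytest

from rppgkit.synthio import VitalParams, generate_trace, snr_noise_sd

FPS = 23.0
HR_BPM = 72.0
RR_BPM = 15.0


@pytest.fixture(scope="session")
def default_params() -> VitalParams:
    return VitalParams()


@pytest.fixture(scope="session")
def noise_sd_10db(default_params) -> float:
    """White-noise s.d. giving 10 dB SNR on the green channel."""
    return snr_noise_sd(default_params, 10.0)


@pytest.fixture(scope="session")
def standard_trace(default_params, noise_sd_10db):
    """The canonical noisy fixture: 60 s @ 23 fps, hr 72, rr 15, 10 dB SNR."""
    params = dataclasses.replace(default_params, seed=0, noise_sd=noise_sd_10db)
    return generate_trace(params)


@pytest.fixture(scope="session")
def clean_trace(default_params):
    params = dataclasses.replace(default_params, seed=0, noise_sd=0.0)
    return generate_trace(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
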