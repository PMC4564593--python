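"""Shared fixtures: one seeded desk-scale bSSFP dataset reused across tests."""

import numpy as np
import pytest

import ktfmri as k

MATRIX = (64, 48)
PHANTOM_SEED = 7
NOISE_SEED = 11
SNR = 20.0


@pytest.fixture(scope="session")
def phantom():
    return k.make_phantom(MATRIX, seed=PHANTOM_SEED)


@pytest.fixture(scope="session")
def paradigm():
    return k.Paradigm.bssfp_default()


@pytest.fixture(scope="session")
def acq():
    return k.AcquisitionConfig.bssfp(phase_cycling=180.0)


@pytest.fixture(scope="session")
def clean_series(phantom, paradigm, acq):
    return k.simulate_timeseries(phantom, paradigm, acq)


@pytest.fixture(scope="session")
def noisy_kspace(clean_series):
    sd = k.noise_sd_for_snr(clean_series, SNR)
    return k.to_kspace(clean_series, noise_sd=sd, seed=NOISE_SEED)


@pytest.fixture(scope="session")
def full_images(noisy_kspace, paradigm):
    return k.ImageSeries(
        k.kspace_to_image(noisy_kspace.data), paradigm=paradigm, provenance="ground_truth"
    )


@pytest.fixture(scope="session")
def grc1_kspace(noisy_kspace, paradigm):
    mask = k.gen_mixture_center1(MATRIX[1], paradigm.n_frames, 4, seed=3)
    return k.apply_mask(noisy_kspace, mask)
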