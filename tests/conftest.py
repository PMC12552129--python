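import numpy as np
import pytest

import specquant as sq
from specquant.synth import sigma_for_snr

GREY_WINDOW = (7.6, 6.6)


@pytest.fixture(scope="session")
def acq_1h():
    return sq.AcquisitionParams(nucleus="1H", sfo_mhz=600.13, sw_ppm=16.0,
                                n_points=8192, carrier_ppm=4.7)


@pytest.fixture
def noiseless_triplet_spectrum():
    """Rescaled, noiseless 30 mM ammonium 1H spectrum (triplet at 7.10 ppm)."""
    sample = sq.AmmoniumSample(conc_14n_mM=30.0)
    return sq.rescale(sq.simulate_1h_spectrum(sample)), sample


def make_pair(sample: sq.AmmoniumSample):
    """Rescaled (1H, 15N) spectra for one sample."""
    return (
        sq.rescale(sq.simulate_1h_spectrum(sample)),
        sq.rescale(sq.simulate_15n_spectrum(sample)),
    )


def noisy_sample(conc_14n, conc_15n, seed, snr_1h=50.0, snr_15n=50.0, **kw):
    """Ammonium sample with per-channel noise chosen to hit the given SNRs."""
    s = sq.AmmoniumSample(conc_14n_mM=conc_14n, conc_15n_mM=conc_15n, seed=seed, **kw)
    s.noise_sigma = sigma_for_snr(s, snr_1h, channel="1H")
    s.noise_sigma_15n = sigma_for_snr(s, snr_15n, channel="15N")
    return s
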