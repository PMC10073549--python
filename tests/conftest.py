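import logging

import numpy as np
import pytest

from ricenni import agronomy as agro
from ricenni import spectra as spec
from ricenni.pipeline import fit_curve_from_agronomy
from ricenni.synthetic_data import simulate_two_experiments

logging.getLogger("ricenni").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def dataset():
    """Default two-experiment synthetic dataset (~200 samples), fixed seed."""
    agronomy, truth, spectra = simulate_two_experiments(3)
    return agronomy, truth, spectra


@pytest.fixture(scope="session")
def curve_and_nni(dataset):
    agronomy, _, _ = dataset
    curve, points, diag = fit_curve_from_agronomy(agronomy)
    nni = agro.compute_nni_table(agronomy, curve)
    return curve, nni


@pytest.fixture(scope="session")
def smoothed_spectra(dataset):
    _, _, spectra = dataset
    return spec.gaussian_denoise(spectra, sigma=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
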