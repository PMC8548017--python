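import numpy as np
import pytest

from tdnirs.forward import (
    DTOF,
    InstrumentConfig,
    IRFModel,
    OpticalProperties,
    diffuse_reflectance_td,
    expected_dtof,
    sample_dtof,
    synthesize_irf,
)


@pytest.fixture(scope="session")
def config():
    return InstrumentConfig()


@pytest.fixture(scope="session")
def irf_model():
    return IRFModel()


@pytest.fixture(scope="session")
def irf_curve(config, irf_model):
    return synthesize_irf(irf_model, config)


@pytest.fixture(scope="session")
def irf_max_time(config, irf_curve):
    return float(config.times()[np.argmax(irf_curve)])


@pytest.fixture(scope="session")
def dtof_factory(config, irf_curve):
    """Simulated DTOF through the full instrument chain."""

    def make(
        mua=0.1,
        musp=10.0,
        n_medium=1.4,
        rho=3.0,
        photons=1e6,
        background=1.0,
        seed=0,
        noiseless=False,
    ):
        props = OpticalProperties(mua, musp, n_medium)
        curve = diffuse_reflectance_td(rho, config.times(), props)
        lam = expected_dtof(curve, irf_curve, photons, background)
        if noiseless:
            return DTOF(counts=lam, bin_width=config.bin_width, rho=rho,
                        background_level=background)
        return sample_dtof(lam, seed, bin_width=config.bin_width, rho=rho,
                           background_level=background)

    return make
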