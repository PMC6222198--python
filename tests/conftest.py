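import logging

import numpy as np
import pytest

import osmoshock as osk

# silence emcee's chain-length advisories in test output
logging.getLogger("emcee").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_config():
    """Standard synthetic study conditions with a fixed seed."""
    return osk.SyntheticConfig(rng_seed=11)


@pytest.fixture(scope="session")
def cells(default_config):
    return osk.generate_cells(default_config)


@pytest.fixture(scope="session")
def calibration_result(default_config):
    """One hierarchical calibration fit on the default candle."""
    replicates, _ = osk.generate_candle(default_config)
    return osk.fit_calibration(
        replicates,
        default_config.candle_mean_copies,
        osk.calibration.CalibrationSamplerConfig(seed=7),
    )


@pytest.fixture(scope="session")
def fitted_posterior(cells):
    """One logistic fit on the default cells using true copy numbers."""
    return osk.fit_single(
        cells["truth__n_channels"],
        cells["survival"],
        sampler=osk.SamplerConfig(seed=13),
    )


@pytest.fixture()
def degenerate_calibration():
    """A point-mass calibration: alpha = 2 a.u./channel, <A> = 4 um^2."""
    return osk.CalibrationResult(
        alpha_samples=np.full(100, 2.0), mean_area_samples=np.full(100, 4.0)
    )
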