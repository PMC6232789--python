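import numpy as np
import pytest

from femri.iron_mapping import IronCalibration, apply_calibration, stratify
from femri.phantom import MRIPhantomConfig, generate_mri_phantom
from femri.relaxometry import fit_monoexponential


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default 256x256 noiseless MGE phantom with 30 planted deposits."""
    config = MRIPhantomConfig(noise_sd=0.0, seed=1)
    series, truth = generate_mri_phantom(config)
    return config, series, truth


@pytest.fixture(scope="session")
def noiseless_femap(noiseless_phantom):
    """Stratified FeMRI map recovered end-to-end from the noiseless phantom."""
    config, series, truth = noiseless_phantom
    r2map = fit_monoexponential(series, mask=truth.tumor_mask)
    cal = IronCalibration(
        slope=config.calibration_slope, intercept=config.calibration_intercept
    )
    return stratify(apply_calibration(r2map, cal, mask=truth.tumor_mask))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
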