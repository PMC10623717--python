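import numpy as np
import pytest

import bowelsound as bs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def calib_recording():
    """A 5-min synthetic calibration recording (no movement artifacts,
    like a clinician-chosen quiet N3 span), denoised, with its truth."""
    cfg = bs.SynthConfig(duration_s=300.0, seed=3, turnover_rate_per_hour=0.0)
    rec, truth = bs.generate(cfg)
    den = bs.denoise_pipeline(rec)
    return rec, den, truth


@pytest.fixture(scope="session")
def calibration_result(calib_recording):
    _, den, truth = calib_recording
    return bs.calibrate_threshold(den.bs, den.fs, truth.ebs)
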