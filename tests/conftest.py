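import numpy as np
import pytest
from hypothesis import settings

from ecctrain.synth import TrialSpec, simulate_active_trial

# deterministic property tests, no on-disk example database
settings.register_profile("deterministic", database=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def active_spec():
    return TrialSpec(
        mode="eccentric", direction="external", target_speed=30.0,
        rom_start=-60.0, rom_end=90.0, accel_time=0.2,
        noise_sd_torque=0.0, seed=3,
    )


@pytest.fixture()
def active_trial(active_spec):
    return simulate_active_trial(active_spec, peak_torque=40.0,
                                 optimum_angle=20.0, n_reps=3)


def smooth_gaussian_curves(rng, n, q=101, fwhm=10.0):
    """Stationary smooth Gaussian noise curves (edge-padded then cropped)."""
    from scipy.ndimage import gaussian_filter1d

    sigma = fwhm / np.sqrt(8.0 * np.log(2.0))
    pad = int(6 * sigma)
    w = rng.standard_normal((n, q + 2 * pad))
    return gaussian_filter1d(w, sigma, axis=-1)[:, pad:pad + q]
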