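"""Shared fixtures: small synthetic scenes and optode experiments."""

import numpy as np
import pytest

import farredo2 as f2


@pytest.fixture(scope="session")
def default_scene():
    """Noiseless beachrock-style scene: chl-a surface layer + chl-f hotspots."""
    return f2.synth_hyperspectral_scene(f2.SceneParams())


@pytest.fixture(scope="session")
def default_reflectance(default_scene):
    sc = default_scene
    return f2.to_reflectance(
        f2.dark_correct(sc.raw, sc.dark),
        f2.dark_correct(sc.standard, sc.standard_dark),
    )


@pytest.fixture(scope="session")
def calibration_model():
    """Exact fit of the generator's default calibration truth."""
    pairs = f2.synth_calibration_series(1.5, 0.02, levels=8, sigma=0.0, seed=1)
    return f2.fit_calibration(pairs[["delta_r", "o2_percent_airsat"]].to_numpy())


def run_optode_pipeline(data, model):
    """Frames → ratios → ΔR (dark-anoxic referenced) → calibrated O2 series."""
    ratios = [f2.ratio_image(fr) for fr in data.frames]
    ref = f2.dark_reference(ratios, before_t=data.params.t_light_on)
    images = [f2.invert_calibration(model, f2.delta_ratio(r, ref)) for r in ratios]
    return f2.O2Series(images, data.events)


@pytest.fixture(scope="session")
def noiseless_optode(calibration_model):
    data = f2.synth_optode_timeseries(f2.OptodeParams())
    return data, run_optode_pipeline(data, calibration_model)


@pytest.fixture(scope="session")
def noisy_optode(calibration_model):
    """Camera noise at SNR = green_level / sigma = 50."""
    data = f2.synth_optode_timeseries(f2.OptodeParams(noise_sigma=20.0, seed=3))
    return data, run_optode_pipeline(data, calibration_model)
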