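"""Shared fixtures: small, fast synthetic scenarios rendered once per session."""

import dataclasses

import numpy as np
import pytest

from oisdyn import synthetic as syn


@pytest.fixture(scope="session")
def small_params():
    """A 64x64 control scenario cheap enough for per-test rendering."""
    return dataclasses.replace(
        syn.CONTROL_PARAMS,
        image_height_px=64,
        image_width_px=64,
        pixel_size_mm=0.06,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_params):
    return syn.generate_vessel_tree(small_params)


@pytest.fixture(scope="session")
def small_trials(small_params, small_truth):
    return syn.render_trials(small_params, small_truth)


@pytest.fixture(scope="session")
def noiseless_params(small_params):
    """Same geometry with noise, oscillations and dilation switched off."""
    return dataclasses.replace(
        small_params,
        noise_sd_pct=0.0,
        osc_components=(),
        dilation_pct=0.0,
        n_trials=2,
    )


@pytest.fixture(scope="session")
def noiseless_trials(noiseless_params):
    truth = syn.generate_vessel_tree(noiseless_params)
    return syn.render_trials(noiseless_params, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
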