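"""Shared fixtures: phantoms are rendered once per session."""

import dataclasses

import pytest
from hypothesis import settings

from tarsalct import default_tarsal_spec, make_phantom, quantify, small_tarsal_spec

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless study-scale phantom: (spec, volume, ground truth)."""
    spec = dataclasses.replace(default_tarsal_spec(), noise_sd=0.0)
    vol, truth = make_phantom(spec, seed=0)
    return spec, vol, truth


@pytest.fixture(scope="session")
def default_quantified(default_phantom):
    """Quantification of the noiseless study-scale phantom."""
    _, vol, _ = default_phantom
    return quantify(vol)


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless reduced phantom (60-slice bone span) for cheap checks."""
    spec = dataclasses.replace(small_tarsal_spec(), noise_sd=0.0)
    vol, truth = make_phantom(spec, seed=0)
    return spec, vol, truth


@pytest.fixture(scope="session")
def noisy_small_phantom():
    """Reduced phantom with the default 50 AU noise."""
    spec = small_tarsal_spec()
    vol, truth = make_phantom(spec, seed=1)
    return spec, vol, truth
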