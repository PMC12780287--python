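"""Shared fixtures: phantom cases generated once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from lgequant import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noise_free_case():
    """Solid 72-degree fully transmural infarct, no noise, no coil bias."""
    return generate_phantom(PhantomSpec(remote_sd=0.0, infarct_sd=0.0))


@pytest.fixture(scope="session")
def noisy_case():
    """Default noisy solid phantom."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def psir_case():
    """PSIR phantom with negative remote mean (sign-preserving)."""
    return generate_phantom(PhantomSpec.psir(seed=5))


@pytest.fixture(scope="session")
def null_case():
    """Infarct-free noisy phantom."""
    return generate_phantom(PhantomSpec(infarct_extent_deg=0.0, seed=3))


@pytest.fixture(scope="session")
def mvo_case():
    """Noise-free phantom with a hypointense subendocardial MVO core."""
    return generate_phantom(
        PhantomSpec(mvo_core_fraction=0.5, remote_sd=0.0, infarct_sd=0.0)
    )


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
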