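"""Shared fixtures: phantoms are generated once per session at sizes that keep
module tests fast; parameter-recovery tests at the full study resolution live
in test_acceptance.py with their own session fixtures."""

import logging

import numpy as np
import pytest

from cardiodti import (
    DiffusionTensorModel,
    PhantomSpec,
    build_geometry,
    build_phantom,
)

logging.getLogger("cardiodti").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def phantom48():
    """Noiseless 48^3 phantom: (spec, dwi, gtab, truth)."""
    spec = PhantomSpec.for_grid(48)
    dwi, gtab, truth = build_phantom(spec)
    return spec, dwi, gtab, truth


@pytest.fixture(scope="session")
def fit48(phantom48):
    _, dwi, gtab, truth = phantom48
    return DiffusionTensorModel(dwi, gtab, mask=truth.myocardium).fit()


@pytest.fixture(scope="session")
def geom48(phantom48):
    _, _, _, truth = phantom48
    return build_geometry(truth.myocardium, truth.cavity, truth.affine)


@pytest.fixture(scope="session")
def phantom32_snr25():
    """Noisy 32^3 phantom with its noiseless twin: (spec, noisy, noiseless, gtab, truth)."""
    import dataclasses

    spec0 = PhantomSpec.for_grid(32)
    dwi0, gtab, truth = build_phantom(spec0)
    spec_n = dataclasses.replace(spec0, snr_b0=25.0, rng_seed=11)
    dwi_n, _, _ = build_phantom(spec_n)
    return spec0, dwi_n, dwi0, gtab, truth


def angular_error(a, b):
    """Absolute axial angle difference in degrees (period 180)."""
    err = np.abs(a - b)
    return np.minimum(err, 180.0 - err)
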