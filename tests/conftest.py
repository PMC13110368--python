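"""Shared fixtures: small synthetic inputs generated at test time."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from pllpquant.synthetic import PrimordiumParams, make_primordium


NOISE_FREE = dict(noise_sd=0.0, photon_scale=float("inf"))


@pytest.fixture(scope="session")
def default_params() -> PrimordiumParams:
    return PrimordiumParams()


@pytest.fixture(scope="session")
def clean_params() -> PrimordiumParams:
    """Default geometry, no noise: exact oracle conditions."""
    return PrimordiumParams(**NOISE_FREE)


@pytest.fixture(scope="session")
def clean_primordium(clean_params):
    """One noise-free default primordium with its ground truth (seed 7)."""
    return make_primordium(clean_params, seed=7)


@pytest.fixture(scope="session")
def noisy_primordium(default_params):
    """One default-noise primordium with its ground truth (seed 7)."""
    return make_primordium(default_params, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def zero_cv(preset):
    """Copy of a genotype preset with zero count variance."""
    return dataclasses.replace(preset, count_cv=0.0)
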