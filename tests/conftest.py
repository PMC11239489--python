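"""Shared fixtures.

The heavy artifacts — ten toy noise2noise training runs and the stronger
refinement-facing denoiser — are session-scoped so the training-dynamics
tests and the acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from blush.volume_io import Volume
from blush.synthetic import PhantomSpec, make_phantom
from blush import experiments

N2N_SEEDS = tuple(range(10))
BENEFIT_SEEDS = tuple(range(1, 11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_volume(rng) -> Volume:
    return Volume(rng.standard_normal((32, 32, 32)).astype(np.float32), 1.5)


@pytest.fixture()
def phantom_and_mask():
    spec = PhantomSpec(n=32, voxel_size=1.5, n_blobs=8,
                       blob_radius_range=(2.0, 5.0), seed=7)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def n2n_outcomes():
    """Ten independent toy noise2noise training runs (fixed seeds)."""
    return {s: experiments.noise2noise_study(s) for s in N2N_SEEDS}


@pytest.fixture(scope="session")
def refinement_model():
    """The stronger toy denoiser used by the refinement studies."""
    return experiments.train_refinement_denoiser(0).model
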