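"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from s2v.synthetic import (
    PhantomSpec,
    make_phantom,
    make_scheme,
    simulate_dataset,
)
from s2v.temporal import SliceTiming


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(shape=(24, 24, 12), voxel_size=2.5)


@pytest.fixture(scope="session")
def small_scheme():
    return make_scheme(n_b0=3, shells=((700.0, 9),), seed=7)


@pytest.fixture(scope="session")
def small_timing(small_spec):
    return SliceTiming.interleaved(small_spec.shape[2])


@pytest.fixture(scope="session")
def small_phantom(small_spec, small_scheme):
    return make_phantom(small_spec, small_scheme)


@pytest.fixture(scope="session")
def clean_dataset(small_spec, small_scheme, small_timing):
    """Noise-free, motion-free small dataset."""
    return simulate_dataset(
        seed=3,
        phantom_spec=small_spec,
        scheme=small_scheme,
        timing=small_timing,
        movement=0.0,
        snr=None,
    )


@pytest.fixture(scope="session")
def moving_dataset(small_spec, small_scheme, small_timing):
    """Large-movement noisy small dataset with ground-truth sidecar."""
    return simulate_dataset(
        seed=3,
        phantom_spec=small_spec,
        scheme=small_scheme,
        timing=small_timing,
        movement="large",
        snr=40.0,
    )
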