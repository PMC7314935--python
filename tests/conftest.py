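"""Shared fixtures: small synthetic scenes and random-mask helpers."""

import numpy as np
import pytest

from scratchquant import BinaryMask, GreyImage, ScratchSimParams


@pytest.fixture(scope="session")
def small_sim_params():
    """A small but fully featured scratch scene (fast to render)."""
    return ScratchSimParams(
        width=400,
        height=300,
        gap_center=200,
        gap_width_0=80,
        fill_fraction={0.0: 0.0, 24.0: 0.5, 48.0: 0.8},
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_mask(rng, height=None, width=None, p=0.5, max_side=64):
    """A random BinaryMask, at most max_side on each side."""
    h = height or int(rng.integers(1, max_side + 1))
    w = width or int(rng.integers(1, max_side + 1))
    return BinaryMask(rng.random((h, w)) < p)


def grey(pixels, **meta):
    return GreyImage(np.asarray(pixels, dtype=float), **meta)
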