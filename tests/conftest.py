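import numpy as np
import pytest

from psfpercept import optics as op
from psfpercept import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def pupil64():
    return op.PupilGrid(diameter=6.0, resolution=64)


@pytest.fixture
def pupil256():
    return op.PupilGrid(diameter=6.0, resolution=256)


@pytest.fixture
def fast_config():
    """Small, quick simulation config for pipeline-level tests."""
    return synth.SimulationConfig(seed=7, grid_resolution=64, psf_bins=61)


def random_wavefront(pupil, rng, amplitude=0.3):
    """Random low/mid-order aberration mix for property tests."""
    coeffs = np.zeros(15)
    coeffs[1:] = rng.normal(0.0, amplitude, size=14)
    return op.zernike_wavefront(coeffs, pupil)


def brute_force_psf(slopes, bins, half_width):
    """Independent per-ray histogram oracle (explicit loop, shared binning)."""
    mask = slopes.grid.mask()
    ax = np.asarray(slopes.slope_x)[mask] * op.RAD_TO_ARCMIN
    ay = np.asarray(slopes.slope_y)[mask] * op.RAD_TO_ARCMIN
    edges = np.linspace(-half_width, half_width, bins + 1)
    counts = np.zeros((bins, bins), dtype=np.int64)
    out = 0
    for x, y in zip(ax, ay):
        ix = np.searchsorted(edges, x, side="right") - 1
        iy = np.searchsorted(edges, y, side="right") - 1
        if x == edges[-1]:
            ix = bins - 1
        if y == edges[-1]:
            iy = bins - 1
        if 0 <= ix < bins and 0 <= iy < bins:
            counts[iy, ix] += 1
        else:
            out += 1
    return counts, out
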