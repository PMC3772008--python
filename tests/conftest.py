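import numpy as np
import pytest

from mnox import dgge, simulate


def noise_free_lane(positions, intensities, lane_id="lane", sigma=0.004, n_samples=2001):
    """Render an analytically known band structure with no noise.

    Band centers land exactly on the sampling grid when positions are
    multiples of 1/(n_samples-1), so peak heights are read back exactly.
    """
    spec = simulate.LaneSpec(
        lane_id=lane_id,
        positions=tuple(positions),
        intensities=tuple(intensities),
        sigma=sigma,
        baseline=0.05,
        noise_sd=0.0,
        n_samples=n_samples,
    )
    return simulate.simulate_lane(spec, seed=0), spec


def band_set(lane_id, positions, probabilities, heights=None):
    """Construct a BandSet directly from positions and probabilities."""
    if heights is None:
        heights = probabilities
    bands = tuple(
        dgge.Band(position=p, peak_height=h, significant_probability=q)
        for p, h, q in zip(positions, heights, probabilities)
    )
    return dgge.BandSet(lane_id=lane_id, bands=bands)


@pytest.fixture
def rng():
    return np.random.default_rng(20230912)


@pytest.fixture
def three_band_lane():
    """Noise-free lane with heights 2:1:1 -> probabilities (0.5, 0.25, 0.25)."""
    profile, spec = noise_free_lane((0.2, 0.5, 0.8), (2.0, 1.0, 1.0))
    return profile, spec
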