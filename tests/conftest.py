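import numpy as np
import pytest

from optmap.simulate import SimulationParams, simulate_channel
from optmap.types import Frame, SkeletalSegment


def make_ridge_frame(n_cols=20, row0=6, height=13, peak=100.0, shoulder=20.0,
                     background=0.0):
    """Frame with one horizontal ridge: vertical profile (bg, shoulder,
    peak, shoulder, bg) centred at ``row0`` in every column."""
    img = np.full((height, n_cols), background, dtype=float)
    img[row0] = background + peak
    img[row0 - 1] = img[row0 + 1] = background + shoulder
    return Frame(pixels=img)


def make_segment(left, right, frame_index=0, mean_intensity=500.0):
    """Straight one-pixel-per-column segment between two end points."""
    (r0, c0), (r1, c1) = left, right
    cols = np.arange(c0, c1 + 1)
    if c1 == c0:
        rows = np.array([r0])
    else:
        rows = np.rint(r0 + (r1 - r0) * (cols - c0) / (c1 - c0)).astype(int)
    return SkeletalSegment(
        pixels=np.column_stack([rows, cols]),
        left_end=(int(rows[0]), int(cols[0])),
        right_end=(int(rows[-1]), int(cols[-1])),
        frame_index=frame_index,
        mean_intensity=mean_intensity,
    )


@pytest.fixture(scope="session")
def small_channel():
    """Small noiseless simulated channel used by several modules' tests."""
    params = SimulationParams(
        frame_shape=(220, 360),
        n_frames=4,
        molecule_density=1.0,
        size_range_kb=(20.0, 60.0),
        standards_per_channel=1,
        noise_sigma_adu=0.0,
        min_row_spacing_px=22,
        seed=42,
    )
    frames, truth = simulate_channel(params)
    return params, frames, truth


@pytest.fixture(scope="session")
def noisy_channel():
    """Same layout with read noise at one tenth of the background."""
    params = SimulationParams(
        frame_shape=(220, 360),
        n_frames=4,
        molecule_density=1.0,
        size_range_kb=(20.0, 60.0),
        standards_per_channel=1,
        noise_sigma_adu=10.0,
        min_row_spacing_px=22,
        seed=42,
    )
    frames, truth = simulate_channel(params)
    return params, frames, truth
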