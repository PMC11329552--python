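import numpy as np
import pytest

from rimotion.signals import DisplacementTrace
from rimotion.surrogate import TimedPointCloud


def flat_plane_cloud(height_m: float, spacing_m: float = 0.001,
                     n_side: int = 11, timestamp: float = 0.0,
                     frame_id: int = 0) -> TimedPointCloud:
    """A square flat grid at a given height, used across surrogate tests."""
    coords = (np.arange(n_side) - (n_side - 1) / 2) * spacing_m
    xx, yy = np.meshgrid(coords, coords)
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, height_m)])
    return TimedPointCloud(points=pts, timestamp=timestamp, frame_id=frame_id)


def brute_force_surrogate_mm(cloud_pts: np.ndarray, ref_pts: np.ndarray) -> float:
    """Independent exhaustive nearest-neighbour oracle (O(N*M) loops)."""
    total = 0.0
    for p in cloud_pts:
        best = min(float(np.sqrt(((p - r) ** 2).sum())) for r in ref_pts)
        total += best
    return total / len(cloud_pts) * 1000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sinusoid_trace():
    """Pure 30 mm peak-to-trough sinusoid at 0.25 Hz, 60 s at 15 Hz."""
    t = np.arange(0, 60, 1 / 15)
    si = 15.0 * (1 - np.cos(2 * np.pi * 0.25 * t))
    return DisplacementTrace(timestamps=t, si_mm=si)
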