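"""Scalar breathing surrogate from abdominal surface point clouds.

The surrogate is the mean distance from every point of the current
surface observation to its closest point in a *reference* cloud captured
at maximum inhalation.  Because the reference sits at one extreme of the
breathing cycle, every other respiratory phase lies on the same side of
it, so the unsigned nearest-neighbour distance rises and falls with the
breathing cycle and serves as the regressor of the correspondence model.

Conventions
-----------
* Point clouds are in metres (as stored on disk); surrogate values are
  reported in millimetres.
* The distance is *directed*, current cloud -> reference.
* A signed variant, projecting the nearest-neighbour offset onto the
  height axis, is available via ``signed=True`` for sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError

__all__ = [
    "TimedPointCloud",
    "ReferenceCloud",
    "SurrogateSeries",
    "select_reference_cloud",
    "compute_surrogate",
    "compute_surrogate_series",
    "voxel_downsample",
]


def _validate_points(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise InvalidArgumentError("points must be an (N, 3) array")
    if points.shape[0] < 3:
        raise InvalidArgumentError("a point cloud needs at least 3 points")
    if not np.all(np.isfinite(points)):
        raise InvalidArgumentError("point coordinates must be finite")
    return points


@dataclass
class TimedPointCloud:
    """One surface observation: (N, 3) points in metres plus a timestamp."""

    points: np.ndarray
    timestamp: float
    frame_id: int = 0

    def __post_init__(self):
        self.points = _validate_points(self.points)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class ReferenceCloud:
    """The maximum-inhalation cloud all frames are compared against."""

    points: np.ndarray
    frame_id: int = 0
    strategy: str = "extreme-height"

    def __post_init__(self):
        self.points = _validate_points(self.points)


@dataclass
class SurrogateSeries:
    """Scalar surrogate x(t) in mm, one value per input frame."""

    timestamps: np.ndarray
    values_mm: np.ndarray
    reference_frame_id: int = 0
    signed: bool = False

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values_mm = np.asarray(self.values_mm, dtype=float)
        if self.timestamps.shape != self.values_mm.shape:
            raise InvalidArgumentError("timestamps and values must have equal length")

    def __len__(self) -> int:
        return self.timestamps.size


def select_reference_cloud(
    sequence: list[TimedPointCloud],
    strategy: str = "extreme-height",
    height_axis: int = 2,
    inhale_sign: float = 1.0,
    index: int | None = None,
) -> ReferenceCloud:
    """Pick the maximum-inhalation frame of a sequence.

    ``"extreme-height"`` selects the frame whose mean coordinate along
    ``height_axis`` is extremal in the inhalation direction given by
    ``inhale_sign`` (+1: inhalation raises the surface towards larger
    coordinates; -1: e.g. a camera above a supine subject, where
    inhalation shortens the camera distance).  Ties are broken by the
    earliest frame.  ``"index"`` returns the user-specified frame.
    """
    if not sequence:
        raise InvalidArgumentError("cannot select a reference from an empty sequence")
    if strategy == "index":
        if index is None:
            raise InvalidArgumentError("strategy 'index' requires an index")
        cloud = sequence[index]
    elif strategy == "extreme-height":
        scores = np.array(
            [inhale_sign * float(np.mean(c.points[:, height_axis])) for c in sequence]
        )
        # argmax returns the first maximum -> earliest frame on ties
        cloud = sequence[int(np.argmax(scores))]
    else:
        raise InvalidArgumentError(f"unknown reference strategy {strategy!r}")
    return ReferenceCloud(points=cloud.points, frame_id=cloud.frame_id, strategy=strategy)


def voxel_downsample(points: np.ndarray, voxel_size: float) -> np.ndarray:
    """Decimate a cloud to one centroid per occupied voxel.

    An optional speed/accuracy trade-off for very dense clouds; the
    surrogate computed on a decimated cloud is an approximation of the
    full-resolution value and is off by default everywhere.
    """
    points = _validate_points(points)
    if voxel_size <= 0:
        raise InvalidArgumentError("voxel_size must be > 0")
    keys = np.floor(points / voxel_size).astype(np.int64)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    n_voxels = inverse.max() + 1
    sums = np.zeros((n_voxels, 3))
    np.add.at(sums, inverse, points)
    counts = np.bincount(inverse, minlength=n_voxels).astype(float)
    return sums / counts[:, None]


def _surrogate_from_tree(
    points: np.ndarray,
    tree: cKDTree,
    ref_points: np.ndarray,
    signed: bool,
    height_axis: int,
    inhale_sign: float,
) -> float:
    dists, idx = tree.query(points, k=1)
    if not signed:
        return float(np.mean(dists)) * 1000.0
    # signed variant: nearest-neighbour offset projected on the height axis,
    # positive when the current surface sits on the exhale side of the reference
    delta = ref_points[idx, height_axis] - points[:, height_axis]
    return float(np.mean(inhale_sign * delta)) * 1000.0


def compute_surrogate(
    cloud: TimedPointCloud | np.ndarray,
    reference: ReferenceCloud | np.ndarray,
    signed: bool = False,
    height_axis: int = 2,
    inhale_sign: float = 1.0,
) -> float:
    """Mean closest-point distance (mm) from ``cloud`` to ``reference``.

    Returns ``(1/N) * sum_i min_j ||p_i - r_j||`` over the N points of the
    current cloud, converted from metres to millimetres.
    """
    pts = cloud.points if isinstance(cloud, TimedPointCloud) else _validate_points(cloud)
    ref = (
        reference.points
        if isinstance(reference, ReferenceCloud)
        else _validate_points(reference)
    )
    tree = cKDTree(ref)
    return _surrogate_from_tree(pts, tree, ref, signed, height_axis, inhale_sign)


def compute_surrogate_series(
    sequence: list[TimedPointCloud],
    reference: ReferenceCloud,
    signed: bool = False,
    height_axis: int = 2,
    inhale_sign: float = 1.0,
    voxel_size: float | None = None,
) -> SurrogateSeries:
    """Apply :func:`compute_surrogate` frame-wise, reusing one spatial index.

    ``voxel_size`` (metres) optionally decimates the *reference* cloud
    with :func:`voxel_downsample` before indexing — an approximation,
    disabled by default.
    """
    if not sequence:
        raise InvalidArgumentError("cannot compute a surrogate series on an empty sequence")
    ref_points = reference.points
    if voxel_size is not None:
        ref_points = voxel_downsample(ref_points, voxel_size)
        reference = ReferenceCloud(
            points=ref_points,
            frame_id=reference.frame_id,
            strategy=reference.strategy,
        )
    tree = cKDTree(ref_points)
    values = np.empty(len(sequence))
    timestamps = np.empty(len(sequence))
    for i, cloud in enumerate(sequence):
        try:
            values[i] = _surrogate_from_tree(
                cloud.points, tree, reference.points, signed, height_axis, inhale_sign
            )
        except Exception as exc:  # pragma: no cover - defensive re-raise with frame id
            raise InvalidArgumentError(
                f"surrogate failed at frame {cloud.frame_id}: {exc}"
            ) from exc
        timestamps[i] = cloud.timestamp
    return SurrogateSeries(
        timestamps=timestamps,
        values_mm=values,
        reference_frame_id=reference.frame_id,
        signed=signed,
    )
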