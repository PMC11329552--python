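"""Ground-truth liver motion from binary segmentation masks.

Segmented ultrasound frames (produced by any external segmenter) are
post-processed — largest connected component, hole filling, morphological
closing — their edges extracted, and the mean edge column inside a region
of interest tracked over time.  Column motion times the pixel spacing
(0.027 cm/px for the reference scanner setup) gives the 1-D
superior-inferior liver displacement.  Segmentation quality is scored
with the Dice coefficient and the (optionally ROI-restricted) symmetric
Hausdorff distance.

Conventions: image coordinates are row-major 0-based ``(row, col)``;
connected components use 8-connectivity and edges 4-connectivity (a
foreground pixel is an edge pixel if any 4-neighbour, or the image
border, is background); ROI ranges are half-open; increasing column is
positive SI displacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sp_signal
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .errors import (
    EmptySegmentationError,
    InvalidArgumentError,
    NoCyclesError,
    TrackingGapError,
)
from .signals import DisplacementTrace

__all__ = [
    "BinaryMask",
    "EdgeSet",
    "RoiBox",
    "FilterConfig",
    "preprocess_image",
    "postprocess_mask",
    "extract_edge",
    "track_displacement",
    "dice",
    "hausdorff",
    "evaluate_segmentation",
    "summarize_displacement",
]


@dataclass
class BinaryMask:
    """A binary segmentation on a rectangular pixel grid."""

    data: np.ndarray
    pixel_spacing: float = 0.027  # cm per pixel, isotropic
    timestamp: float = 0.0
    frame_id: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise InvalidArgumentError("mask must be a 2-D array")
        if self.pixel_spacing <= 0:
            raise InvalidArgumentError("pixel_spacing must be > 0")

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


@dataclass
class EdgeSet:
    """Boundary pixels of a mask's foreground, as (row, col) pairs."""

    pixels: np.ndarray
    frame_id: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)
        if self.pixels.shape[0] == 0:
            raise InvalidArgumentError("an EdgeSet cannot be empty")

    def __len__(self) -> int:
        return self.pixels.shape[0]


@dataclass
class RoiBox:
    """Half-open pixel box [row0, row1) x [col0, col1)."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self):
        if self.row0 >= self.row1 or self.col0 >= self.col1:
            raise InvalidArgumentError("RoiBox ranges must be non-empty")

    def contains(self, pixels: np.ndarray) -> np.ndarray:
        r, c = pixels[:, 0], pixels[:, 1]
        return (r >= self.row0) & (r < self.row1) & (c >= self.col0) & (c < self.col1)


@dataclass
class FilterConfig:
    """Zero-phase low-pass smoothing of the tracked 1-D signal.

    Forward-backward second-order Butterworth.  The default 1 Hz cutoff
    sits well above the breathing band (0.1-0.5 Hz) and below
    pixel-quantisation chatter.  ``enabled=False`` disables smoothing.
    """

    enabled: bool = True
    cutoff_hz: float = 1.0
    order: int = 2


def _as_mask_array(mask: BinaryMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.data
    return np.asarray(mask).astype(bool)


def preprocess_image(image: np.ndarray, crop: RoiBox) -> np.ndarray:
    """Percentile contrast stretch (1st-99th -> [0, 1]) and crop.

    Provided for completeness so a pluggable segmenter receives frames
    in the standard 512 x 512 cropped form; a degenerate (constant)
    stretch maps everything to 0.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidArgumentError("image must be 2-D")
    rows, cols = image.shape
    if crop.row0 < 0 or crop.col0 < 0 or crop.row1 > rows or crop.col1 > cols:
        raise InvalidArgumentError("crop box outside image")
    out = image[crop.row0 : crop.row1, crop.col0 : crop.col1]
    lo, hi = np.percentile(out, [1.0, 99.0])
    if hi <= lo:
        return np.zeros_like(out)
    return np.clip((out - lo) / (hi - lo), 0.0, 1.0)


def postprocess_mask(
    mask: BinaryMask | np.ndarray, closing_radius: int = 2
) -> BinaryMask:
    """Largest 8-connected component, holes filled, then binary closing.

    Ties between equal-sized components go to the one whose first pixel
    comes earliest in row-major order.  Raises
    :class:`EmptySegmentationError` on an empty mask.
    """
    data = _as_mask_array(mask)
    frame_id = mask.frame_id if isinstance(mask, BinaryMask) else 0
    if not data.any():
        raise EmptySegmentationError(
            f"empty segmentation at frame {frame_id}", frame_id=frame_id
        )
    labels = measure.label(data, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if tied.size > 1:
        # earliest first-pixel in row-major order wins
        first = {lab: np.argmax(labels.ravel() == lab) for lab in tied}
        keep = min(tied, key=lambda lab: first[lab])
    else:
        keep = tied[0]
    out = labels == keep
    out = ndimage.binary_fill_holes(out)
    if closing_radius > 0:
        out = morphology.closing(out, morphology.disk(closing_radius))
        out = ndimage.binary_fill_holes(out)
    if isinstance(mask, BinaryMask):
        return BinaryMask(
            data=out,
            pixel_spacing=mask.pixel_spacing,
            timestamp=mask.timestamp,
            frame_id=mask.frame_id,
        )
    return BinaryMask(data=out)


def extract_edge(mask: BinaryMask | np.ndarray) -> EdgeSet:
    """Foreground pixels with a 4-connected background neighbour.

    The image border counts as background, so a mask touching the border
    contributes its border pixels as edges.
    """
    data = _as_mask_array(mask)
    frame_id = mask.frame_id if isinstance(mask, BinaryMask) else 0
    if not data.any():
        raise EmptySegmentationError(
            f"cannot extract edges of an empty mask (frame {frame_id})",
            frame_id=frame_id,
        )
    padded = np.pad(data, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    edge = data & ~interior
    rows, cols = np.nonzero(edge)
    return EdgeSet(pixels=np.column_stack([rows, cols]), frame_id=frame_id)


def _edge_pixels(edges: EdgeSet | np.ndarray) -> np.ndarray:
    if isinstance(edges, EdgeSet):
        return edges.pixels
    return np.asarray(edges, dtype=int).reshape(-1, 2)


def track_displacement(
    edges: list[EdgeSet],
    roi: RoiBox,
    pixel_spacing: float = 0.027,
    filter_cfg: FilterConfig | None = None,
    timestamps: np.ndarray | None = None,
    summary: str = "mean",
    max_gap: int = 0,
) -> DisplacementTrace:
    """Track the liver edge column inside the ROI over a mask sequence.

    Per frame the tracked coordinate is the mean (or median) column of
    the edge pixels inside ``roi``; displacement is
    ``(coord - coord_0) * pixel_spacing`` cm, reported in mm, optionally
    smoothed with a zero-phase low-pass filter.  A frame with no edge
    pixel in the ROI raises :class:`TrackingGapError` unless the gap can
    be linearly interpolated over (``max_gap`` consecutive frames).
    """
    if not edges:
        raise InvalidArgumentError("empty edge sequence")
    if pixel_spacing <= 0:
        raise InvalidArgumentError("pixel_spacing must be > 0")
    if summary not in ("mean", "median"):
        raise InvalidArgumentError("summary must be 'mean' or 'median'")
    n = len(edges)
    if timestamps is None:
        timestamps = np.arange(n, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps.shape != (n,):
        raise InvalidArgumentError("timestamps must match the edge sequence length")

    coords = np.full(n, np.nan)
    for i, es in enumerate(edges):
        px = _edge_pixels(es)
        inside = px[roi.contains(px)]
        if inside.shape[0] > 0:
            col = inside[:, 1].astype(float)
            coords[i] = np.mean(col) if summary == "mean" else np.median(col)
    missing = np.isnan(coords)
    if missing.any():
        longest = run = 0
        for m in missing:
            run = run + 1 if m else 0
            longest = max(longest, run)
        if longest > max_gap or missing[0] or missing[-1]:
            bad = int(np.flatnonzero(missing)[0])
            raise TrackingGapError(
                f"no edge pixels inside ROI at frame {bad}", frame_id=bad
            )
        coords[missing] = np.interp(
            timestamps[missing], timestamps[~missing], coords[~missing]
        )

    disp_cm = (coords - coords[0]) * pixel_spacing
    disp_mm = disp_cm * 10.0
    if filter_cfg is not None and filter_cfg.enabled and n > 3 * filter_cfg.order:
        fs = (n - 1) / (timestamps[-1] - timestamps[0])
        wn = filter_cfg.cutoff_hz / (fs / 2.0)
        if wn < 1.0:
            b, a = sp_signal.butter(filter_cfg.order, wn)
            disp_mm = sp_signal.filtfilt(b, a, disp_mm)
    return DisplacementTrace(timestamps=timestamps, si_mm=disp_mm)


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap ``100 * 2|A n B| / (|A| + |B|)`` in percent."""
    da, db = _as_mask_array(a), _as_mask_array(b)
    if da.shape != db.shape:
        raise InvalidArgumentError("masks must share a shape")
    total = da.sum() + db.sum()
    if total == 0:
        warnings.warn("Dice undefined for two empty masks; returning nan")
        return float("nan")
    return 100.0 * 2.0 * np.logical_and(da, db).sum() / total


def hausdorff(
    a: EdgeSet | np.ndarray,
    b: EdgeSet | np.ndarray,
    pixel_spacing: float = 0.027,
    roi: RoiBox | None = None,
    units: str = "mm",
) -> float:
    """Symmetric Hausdorff distance between two edge sets.

    ``max(max_a min_b d, max_b min_a d)`` in Euclidean pixel distance;
    with ``units="mm"`` the pixel value is multiplied by
    ``pixel_spacing * 10``.  The ROI variant restricts *both* sets to the
    box before comparing.
    """
    pa, pb = _edge_pixels(a), _edge_pixels(b)
    if roi is not None:
        pa = pa[roi.contains(pa)]
        pb = pb[roi.contains(pb)]
        if pa.shape[0] == 0:
            raise InvalidArgumentError("first edge set empty after ROI restriction")
        if pb.shape[0] == 0:
            raise InvalidArgumentError("second edge set empty after ROI restriction")
    d_ab = cKDTree(pb.astype(float)).query(pa.astype(float), k=1)[0].max()
    d_ba = cKDTree(pa.astype(float)).query(pb.astype(float), k=1)[0].max()
    hd_px = float(max(d_ab, d_ba))
    if units == "px":
        return hd_px
    if units == "mm":
        return hd_px * pixel_spacing * 10.0
    raise InvalidArgumentError("units must be 'mm' or 'px'")


def evaluate_segmentation(
    masks: list[BinaryMask],
    references: list[BinaryMask],
    n_samples: int = 20,
    seed: int = 0,
    roi: RoiBox | None = None,
    pixel_spacing: float | None = None,
) -> dict:
    """Dice / Hausdorff / ROI-Hausdorff on a random sample of frames.

    Samples ``n_samples`` frame indices without replacement (seeded); if
    the sequence is shorter, all frames are used and a warning is
    recorded in the result.  Metrics are aggregated mean +/- sd (ddof 1).
    """
    if len(masks) != len(references):
        raise InvalidArgumentError("masks and references must be aligned")
    if len(masks) == 0:
        raise InvalidArgumentError("empty sequences")
    warnings_list: list[str] = []
    n_frames = len(masks)
    if n_frames < n_samples:
        warnings_list.append(
            f"only {n_frames} frames available; using all instead of {n_samples}"
        )
        idx = np.arange(n_frames)
    else:
        idx = np.sort(
            np.random.default_rng(seed).choice(n_frames, size=n_samples, replace=False)
        )
    spacing = pixel_spacing if pixel_spacing is not None else masks[0].pixel_spacing
    rows = []
    for i in idx:
        ea, eb = extract_edge(masks[i]), extract_edge(references[i])
        row = {
            "frame": int(i),
            "dice_pct": dice(masks[i], references[i]),
            "hausdorff_px": hausdorff(ea, eb, spacing, units="px"),
        }
        row["hausdorff_mm"] = row["hausdorff_px"] * spacing * 10.0
        if roi is not None:
            row["hausdorff_roi_px"] = hausdorff(ea, eb, spacing, roi=roi, units="px")
            row["hausdorff_roi_mm"] = row["hausdorff_roi_px"] * spacing * 10.0
        rows.append(row)

    def _agg(key):
        vals = np.array([r[key] for r in rows])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return {"mean": float(np.mean(vals)), "sd": sd}

    result = {
        "n_samples": len(rows),
        "frames": [r["frame"] for r in rows],
        "dice_pct": _agg("dice_pct"),
        "hausdorff_px": _agg("hausdorff_px"),
        "hausdorff_mm": _agg("hausdorff_mm"),
        "per_frame": rows,
        "warnings": warnings_list,
    }
    if roi is not None:
        result["hausdorff_roi_px"] = _agg("hausdorff_roi_px")
        result["hausdorff_roi_mm"] = _agg("hausdorff_roi_mm")
    return result


def summarize_displacement(
    trace: DisplacementTrace, min_prominence_frac: float = 0.25
) -> dict:
    """Per-cycle peak-to-trough amplitudes, mean +/- sd.

    Peaks and troughs are detected with a prominence threshold of
    ``min_prominence_frac`` times the global range; each adjacent
    peak/trough pair contributes one amplitude.  Raises
    :class:`NoCyclesError` when no cycle is detectable.
    """
    y = trace.si_mm
    rng_y = float(y.max() - y.min())
    if rng_y <= 0:
        raise NoCyclesError("constant trace: no breathing cycles")
    prom = min_prominence_frac * rng_y
    peaks, _ = sp_signal.find_peaks(y, prominence=prom)
    troughs, _ = sp_signal.find_peaks(-y, prominence=prom)
    # the trace ends count as extrema so first/last half-cycles are used
    candidates = {0, len(y) - 1} | set(peaks.tolist()) | set(troughs.tolist())
    extrema = np.array(sorted(candidates))
    amplitudes = []
    for i in range(len(extrema) - 1):
        a, b = extrema[i], extrema[i + 1]
        delta = abs(float(y[b] - y[a]))
        if delta >= prom:  # skip flat end segments
            amplitudes.append(delta)
    if not amplitudes:
        raise NoCyclesError("no breathing cycles detected")
    amplitudes = np.asarray(amplitudes)
    sd = float(np.std(amplitudes, ddof=1)) if len(amplitudes) > 1 else 0.0
    return {
        "n_cycles": int(len(amplitudes)),
        "amplitude_mean_mm": float(np.mean(amplitudes)),
        "amplitude_sd_mm": sd,
        "amplitudes_mm": amplitudes,
    }
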