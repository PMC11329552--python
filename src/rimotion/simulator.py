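"""Synthetic phantom and multi-session breathing data.

This module generates everything the estimation pipeline consumes:

* internal displacement traces (the robotic phantom's 30 mm SI / 10 mm AP
  motion at 0.25 Hz, or subject-specific clinical breathing),
* sequences of abdominal-surface point clouds as a depth camera would
  observe them (a smooth patch whose elevation is coupled to the AP
  internal displacement, with optional per-point depth noise),
* binary liver-mask sequences whose right edge moves along the image
  x-axis with the SI displacement, emulating segmented ultrasound,
* multi-session protocols: sessions of free breathing bounded by
  breath-holds, with per-session amplitude scaling, baseline shift and
  breathing-period jitter to emulate inter-fraction variation.

Waveforms
---------
Two cycle shapes are available.  The default ``raised-cosine-power``
profile, ``w(phi) = sin^4(pi * phi)`` with ``phi`` the phase in cycles,
spends more time near the trough than a sinusoid, mimicking the exhale
plateau of spontaneous breathing.  ``sinusoid`` gives
``w(phi) = (1 - cos(2 pi phi)) / 2``.  Both are normalised to [0, 1]
with the trough at phase 0, so a trace is
``baseline + amplitude * w(phi(t))`` and the configured amplitude is the
peak-to-trough excursion.  Breath-holds are modelled at end-exhale
(flat at the trough), so session traces start and end at the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError
from .signals import DisplacementTrace
from .surrogate import TimedPointCloud
from .ustrack import BinaryMask

__all__ = [
    "BreathingParams",
    "SessionVariability",
    "SurfacePatchModel",
    "ProtocolSpec",
    "SessionRaw",
    "simulate_breathing_trace",
    "simulate_surface_sequence",
    "simulate_mask_sequence",
    "simulate_session_set",
]

_WAVEFORMS = ("raised-cosine-power", "sinusoid")


@dataclass
class BreathingParams:
    """Kinematics of the periodic internal motion.

    Amplitudes are peak-to-trough in mm.  ``noise_sd`` is the standard
    deviation of additive Gaussian noise on the observed displacements.
    ``phase_ap_cycles`` offsets the AP channel relative to SI (the
    default 0 moves both axes in phase).
    """

    amplitude_si: float = 30.0
    amplitude_ap: float = 10.0
    frequency: float = 0.25
    waveform: str = "raised-cosine-power"
    noise_sd: float = 0.0
    seed: int = 0
    phase_ap_cycles: float = 0.0

    def __post_init__(self):
        if self.amplitude_si < 0 or self.amplitude_ap < 0:
            raise InvalidArgumentError("amplitudes must be >= 0")
        if self.frequency <= 0:
            raise InvalidArgumentError("frequency must be > 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if self.waveform not in _WAVEFORMS:
            raise InvalidArgumentError(
                f"waveform must be one of {_WAVEFORMS}, got {self.waveform!r}"
            )


@dataclass
class SessionVariability:
    """Per-session departure from the subject's nominal breathing."""

    amplitude_scale: float = 1.0
    baseline_shift: float = 0.0  # mm
    frequency_jitter: float = 0.0  # fractional per-cycle period perturbation

    def __post_init__(self):
        if self.amplitude_scale <= 0:
            raise InvalidArgumentError("amplitude_scale must be > 0")
        if self.frequency_jitter < 0:
            raise InvalidArgumentError("frequency_jitter must be >= 0")


@dataclass
class SurfacePatchModel:
    """The abdominal surface patch seen by the depth camera.

    A square grid of ``extent x extent`` metres at ``spacing`` metres,
    with a smooth Gaussian bump rest profile of height ``bump_height``.
    The whole patch is elevated by ``coupling`` mm per mm of internal AP
    displacement; each observed point carries Gaussian depth noise of
    ``depth_noise_sd`` metres (default 1 mm, consumer depth-camera scale).
    """

    extent: float = 0.30
    spacing: float = 0.015
    bump_height: float = 0.02
    coupling: float = 1.0
    depth_noise_sd: float = 0.001

    def __post_init__(self):
        if self.spacing <= 0 or self.extent <= 0:
            raise InvalidArgumentError("extent and spacing must be > 0")
        if self.coupling == 0:
            raise InvalidArgumentError("coupling must be non-zero")
        if self.depth_noise_sd < 0:
            raise InvalidArgumentError("depth_noise_sd must be >= 0")

    def rest_grid(self) -> np.ndarray:
        """(N, 3) rest-position points in metres."""
        half = self.extent / 2.0
        coords = np.arange(-half, half + self.spacing / 2, self.spacing)
        xx, yy = np.meshgrid(coords, coords)
        sigma = self.extent / 4.0
        zz = self.bump_height * np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


@dataclass
class ProtocolSpec:
    """Multi-session recording protocol.

    Each session lasts ``session_duration`` seconds and starts and ends
    with a flat breath-hold of ``breathhold_duration`` seconds.  The
    surface stream is sampled at ``surrogate_rate`` (depth camera) and
    the internal ground truth at ``groundtruth_rate`` (ultrasound).
    """

    session_duration: float = 60.0
    n_sessions: int = 3
    breathhold_duration: float = 5.0
    surrogate_rate: float = 30.0
    groundtruth_rate: float = 15.0

    def __post_init__(self):
        if self.session_duration <= 0 or self.breathhold_duration < 0:
            raise InvalidArgumentError("durations must be positive")
        if self.surrogate_rate <= 0 or self.groundtruth_rate <= 0:
            raise InvalidArgumentError("rates must be > 0")
        if self.n_sessions < 1:
            raise InvalidArgumentError("n_sessions must be >= 1")
        if 2 * self.breathhold_duration >= self.session_duration:
            raise InvalidArgumentError("breath-holds leave no breathing segment")


def _waveform(phase_cycles: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sinusoid":
        return 0.5 * (1.0 - np.cos(2 * np.pi * phase_cycles))
    if kind == "raised-cosine-power":
        return np.sin(np.pi * phase_cycles) ** 4
    raise InvalidArgumentError(f"unknown waveform {kind!r}")


def simulate_breathing_trace(
    params: BreathingParams, duration: float, rate: float
) -> DisplacementTrace:
    """Periodic phantom-style trace: both axes oscillate continuously.

    The trace starts at the trough (phase 0); with zero noise the
    sampled peak-to-trough equals the configured amplitude up to the
    discretisation of the sampling grid.
    """
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be > 0")
    n = int(round(duration * rate))
    if n < 2:
        raise InvalidArgumentError("duration * rate must give at least 2 samples")
    t = np.arange(n) / rate
    phase = params.frequency * t
    si = params.amplitude_si * _waveform(phase, params.waveform)
    ap = params.amplitude_ap * _waveform(phase + params.phase_ap_cycles, params.waveform)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        si = si + rng.normal(0.0, params.noise_sd, n)
        ap = ap + rng.normal(0.0, params.noise_sd, n)
    return DisplacementTrace(timestamps=t, si_mm=si, ap_mm=ap)


def simulate_surface_sequence(
    trace: DisplacementTrace,
    patch: SurfacePatchModel,
    rate: float,
    seed: int = 0,
) -> list[TimedPointCloud]:
    """Surface clouds: the rest patch elevated by ``coupling * AP(t)``.

    Frame timestamps are spaced ``1/rate`` within the trace's time span;
    the AP channel is linearly interpolated onto them.  Every frame has
    the same point count.
    """
    if len(trace) == 0:
        raise InvalidArgumentError("empty trace")
    if trace.ap_mm is None:
        raise InvalidArgumentError("surface simulation needs an AP channel")
    if rate <= 0:
        raise InvalidArgumentError("rate must be > 0")
    t0, t1 = trace.timestamps[0], trace.timestamps[-1]
    n = int(np.floor((t1 - t0) * rate)) + 1
    times = t0 + np.arange(n) / rate
    ap = np.interp(times, trace.timestamps, trace.ap_mm)
    rest = patch.rest_grid()
    rng = np.random.default_rng(seed)
    clouds = []
    for i in range(n):
        pts = rest.copy()
        pts[:, 2] += patch.coupling * ap[i] / 1000.0  # mm internal -> m surface
        if patch.depth_noise_sd > 0:
            pts[:, 2] += rng.normal(0.0, patch.depth_noise_sd, pts.shape[0])
        clouds.append(TimedPointCloud(points=pts, timestamp=float(times[i]), frame_id=i))
    return clouds


def simulate_mask_sequence(
    trace: DisplacementTrace,
    image_size: tuple[int, int] = (64, 320),
    pixel_spacing: float = 0.027,
    edge_shape: np.ndarray | None = None,
    rest_col: int = 40,
    row_range: tuple[int, int] | None = None,
) -> list[BinaryMask]:
    """Binary masks whose right edge follows the SI displacement.

    Each mask fills columns ``0 .. edge_col(row, t)`` over ``row_range``,
    where ``edge_col = round(rest_col + edge_shape[row] + SI_cm(t) /
    pixel_spacing)``; masks are single connected components without
    holes.  ``edge_shape`` (pixels, one entry per row of the range)
    defaults to a gentle parabolic bow so the edge is not a straight
    line.
    """
    rows, cols = image_size
    if rows < 2 or cols < 2:
        raise InvalidArgumentError("image_size must be at least 2x2")
    if pixel_spacing <= 0:
        raise InvalidArgumentError("pixel_spacing must be > 0")
    if row_range is None:
        row_range = (rows // 8, rows - rows // 8)
    r0, r1 = row_range
    if not (0 <= r0 < r1 <= rows):
        raise InvalidArgumentError("row_range outside image")
    n_rows = r1 - r0
    if edge_shape is None:
        rr = np.arange(n_rows)
        mid = (n_rows - 1) / 2.0
        edge_shape = 3.0 * (1.0 - ((rr - mid) / max(mid, 1.0)) ** 2)
    edge_shape = np.asarray(edge_shape, dtype=float)
    if edge_shape.shape != (n_rows,):
        raise InvalidArgumentError("edge_shape must have one entry per row of row_range")

    disp_px = trace.si_cm / pixel_spacing
    edge_cols = np.round(rest_col + edge_shape[None, :] + disp_px[:, None]).astype(int)
    if edge_cols.min() < 1 or edge_cols.max() >= cols:
        raise InvalidArgumentError(
            "trace excursion moves the mask edge outside the image; "
            "enlarge image_size or rest_col margins"
        )
    col_idx = np.arange(cols)
    masks = []
    for i in range(len(trace)):
        data = np.zeros((rows, cols), dtype=bool)
        data[r0:r1] = col_idx[None, :] <= edge_cols[i][:, None]
        masks.append(
            BinaryMask(
                data=data,
                pixel_spacing=pixel_spacing,
                timestamp=float(trace.timestamps[i]),
                frame_id=i,
            )
        )
    return masks


def _session_phase(
    breathing_span: float,
    frequency: float,
    jitter: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Cycle boundaries and per-cycle periods filling ``breathing_span``.

    The number of cycles is rounded so the breathing segment starts and
    ends exactly at the trough (continuity with end-exhale holds).
    Per-cycle periods are perturbed by ``jitter`` fractionally and then
    rescaled to fill the span.
    """
    n_cycles = max(1, int(round(frequency * breathing_span)))
    periods = np.full(n_cycles, breathing_span / n_cycles)
    if jitter > 0:
        pert = np.clip(rng.normal(0.0, jitter, n_cycles), -0.9, 0.9)
        periods = periods * (1.0 + pert)
        periods *= breathing_span / periods.sum()
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    return boundaries, periods


def _phase_at(t: np.ndarray, boundaries: np.ndarray, periods: np.ndarray) -> np.ndarray:
    """Piecewise-linear phase in cycles over jittered cycle boundaries."""
    k = np.clip(np.searchsorted(boundaries, t, side="right") - 1, 0, len(periods) - 1)
    return k + (t - boundaries[k]) / periods[k]


def simulate_session_trace(
    params: BreathingParams,
    variability: SessionVariability,
    protocol: ProtocolSpec,
    rate: float,
    seed: int,
) -> DisplacementTrace:
    """One session: hold, breathing segment, hold; scaled and shifted."""
    n = int(round(protocol.session_duration * rate))
    t = np.arange(n) / rate
    hold = protocol.breathhold_duration
    span = protocol.session_duration - 2 * hold
    rng = np.random.default_rng(seed)
    boundaries, periods = _session_phase(
        span, params.frequency, variability.frequency_jitter, rng
    )
    w = np.zeros(n)
    # exclusive upper bound: phase n_cycles evaluates to an O(1e-60)
    # residue of sin(pi * n)^4, but a hold sample must be exactly flat
    in_breath = (t >= hold) & (t < hold + span)
    phase = _phase_at(t[in_breath] - hold, boundaries, periods)
    w[in_breath] = _waveform(phase, params.waveform)
    scale = variability.amplitude_scale
    shift = variability.baseline_shift
    si = shift + scale * params.amplitude_si * w
    if params.phase_ap_cycles == 0.0:
        w_ap = w
    else:
        w_ap = np.zeros(n)
        w_ap[in_breath] = _waveform(phase + params.phase_ap_cycles, params.waveform)
    ap = shift + scale * params.amplitude_ap * w_ap
    if params.noise_sd > 0:
        si = si + rng.normal(0.0, params.noise_sd, n)
        ap = ap + rng.normal(0.0, params.noise_sd, n)
    return DisplacementTrace(timestamps=t, si_mm=si, ap_mm=ap)


@dataclass
class SessionRaw:
    """Raw materials of one simulated session."""

    session_id: int
    trace_surrogate_rate: DisplacementTrace  # drives the surface stream
    trace_groundtruth_rate: DisplacementTrace  # drives the mask stream
    clouds: list[TimedPointCloud]
    masks: list[BinaryMask]
    seed: int = 0


def simulate_session_set(
    params: BreathingParams,
    protocol: ProtocolSpec,
    variability: Sequence[SessionVariability],
    patch: SurfacePatchModel | None = None,
    mask_image_size: tuple[int, int] = (64, 320),
    mask_pixel_spacing: float = 0.027,
    mask_rest_col: int = 40,
) -> list[SessionRaw]:
    """Generate every session of a multi-session recording.

    Session ``k`` uses seed ``params.seed + k`` so sessions are
    independent but individually reproducible, and its trace is
    ``amplitude * amplitude_scale_k + baseline_shift_k`` with flat
    end-exhale holds at both ends.
    """
    if len(variability) != protocol.n_sessions:
        raise InvalidArgumentError(
            f"need one SessionVariability per session "
            f"({protocol.n_sessions}), got {len(variability)}"
        )
    if patch is None:
        patch = SurfacePatchModel()
    sessions = []
    for k, var in enumerate(variability):
        seed = params.seed + k
        trace_hi = simulate_session_trace(params, var, protocol, protocol.surrogate_rate, seed)
        trace_gt = simulate_session_trace(params, var, protocol, protocol.groundtruth_rate, seed)
        clouds = simulate_surface_sequence(
            trace_hi, patch, protocol.surrogate_rate, seed=seed
        )
        masks = simulate_mask_sequence(
            trace_gt,
            image_size=mask_image_size,
            pixel_spacing=mask_pixel_spacing,
            rest_col=mask_rest_col,
        )
        sessions.append(
            SessionRaw(
                session_id=k + 1,
                trace_surrogate_rate=trace_hi,
                trace_groundtruth_rate=trace_gt,
                clouds=clouds,
                masks=masks,
                seed=seed,
            )
        )
    return sessions
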