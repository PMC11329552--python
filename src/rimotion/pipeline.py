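"""End-to-end orchestration: synchronization, experiments, cohort tables.

The surrogate stream (depth camera, ~30 Hz) and the ground-truth stream
(EM tracker at 40 Hz or ultrasound-derived at 15 Hz) are aligned onto
one timeline — the surrogate's, which is resampled least — either
directly through timestamps or by matching the end of the leading
breath-hold in both streams.  Breath-hold samples are flagged and
excluded from model fitting but kept in the session record.

Two turnkey experiments mirror the validation studies:

* :func:`run_phantom_experiment` — periodic 30 mm SI / 10 mm AP motion
  at 0.25 Hz, one specific-regime model per axis (a periodic phantom
  gives the single/combined regimes nothing extra to generalise over);
* :func:`run_clinical_experiment` — a cohort of subjects, three
  one-minute sessions each bounded by breath-holds, with inter-session
  amplitude/baseline drift; single, specific and combined regimes per
  subject plus equal-weight overall rows.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import correspondence as cm
from . import simulator as sim
from . import surrogate as sg
from . import ustrack as ut
from .errors import InvalidArgumentError, SynchronizationError
from .signals import DisplacementTrace

__all__ = [
    "StreamPair",
    "PhantomConfig",
    "ClinicalConfig",
    "detect_breathholds",
    "synchronize",
    "run_phantom_experiment",
    "run_clinical_experiment",
    "summarize_cohort",
    "overall_from_session_means",
]


@dataclass
class StreamPair:
    """Unsynchronized surrogate + ground-truth streams of one recording."""

    surrogate: sg.SurrogateSeries
    ground_truth: DisplacementTrace
    session_id: int = 1


def _rolling_variance(values: np.ndarray, half: int) -> np.ndarray:
    """Centred rolling sample variance with truncated edge windows."""
    n = values.size
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    csum2 = np.concatenate([[0.0], np.cumsum(values**2)])
    for i in range(n):
        a, b = max(0, i - half), min(n, i + half + 1)
        m = b - a
        mean = (csum[b] - csum[a]) / m
        out[i] = max(0.0, (csum2[b] - csum2[a]) / m - mean**2)
    return out


def detect_breathholds(
    timestamps: np.ndarray,
    values: np.ndarray,
    window: float = 2.0,
    variance_threshold: float = 0.5,
    presmooth: bool = True,
) -> list[tuple[float, float]]:
    """Low-variance windows of a breathing signal, as (start, end) times.

    A sample belongs to a hold candidate when the sample variance of the
    centred ``window``-second neighbourhood falls below
    ``variance_threshold`` (mm^2); contiguous candidates are merged.
    ``presmooth`` averages the signal over ``window / 2`` first so
    sensor noise does not mask a genuine hold.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 4:
        return []
    span = timestamps[-1] - timestamps[0]
    if span < 2 * window:
        raise InvalidArgumentError("trace must be at least 2 windows long")
    fs = (n - 1) / span
    if presmooth:
        k = max(1, int(round(window / 2 * fs)))
        kernel = np.ones(k) / k
        values = np.convolve(values, kernel, mode="same")
    half = max(1, int(round(window * fs / 2)))
    low = _rolling_variance(values, half) < variance_threshold
    holds = []
    start = None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            holds.append((float(timestamps[start]), float(timestamps[i - 1])))
            start = None
    if start is not None:
        holds.append((float(timestamps[start]), float(timestamps[-1])))
    return holds


def _leading_hold_end(
    timestamps: np.ndarray,
    values: np.ndarray,
    window: float,
    threshold: float,
    departure_frac: float = 0.1,
) -> tuple[float, list[tuple[float, float]]]:
    """Time at which breathing resumes after the leading breath-hold.

    The variance-based hold window only brackets the hold; its edge lags
    by an amount that depends on the stream's amplitude and noise, which
    would bias the inter-stream offset.  Instead, the hold *end* is the
    (sub-sample, linearly interpolated) time at which the smoothed
    signal first departs from the hold level by ``departure_frac`` of
    the stream's full range — a phase point shared by any two streams
    that are affine images of the same breathing waveform.
    """
    holds = detect_breathholds(timestamps, values, window, threshold)
    span = timestamps[-1] - timestamps[0]
    lead = [h for h in holds if h[0] <= timestamps[0] + 0.25 * span]
    if not lead:
        raise SynchronizationError("no leading breath-hold found in stream")
    h0, h1 = lead[0]
    fs = (values.size - 1) / span
    k = max(1, int(round(window / 4 * fs)))
    smooth = np.convolve(values, np.ones(k) / k, mode="same")
    in_hold = (timestamps >= h0) & (timestamps <= h1)
    level = float(np.median(smooth[in_hold]))
    dep = np.abs(smooth - level)
    thresh = departure_frac * float(smooth.max() - smooth.min())
    start = int(np.searchsorted(timestamps, h0))
    above = np.flatnonzero(dep[start:] > thresh)
    if above.size == 0:
        raise SynchronizationError("signal never departs from the leading hold")
    i = start + above[0]
    if i == 0:
        return float(timestamps[0]), holds
    # linear interpolation of the threshold crossing between samples
    d0, d1 = dep[i - 1], dep[i]
    t0, t1 = timestamps[i - 1], timestamps[i]
    frac = 0.0 if d1 == d0 else (thresh - d0) / (d1 - d0)
    return float(t0 + np.clip(frac, 0.0, 1.0) * (t1 - t0)), holds


def synchronize(
    pair: StreamPair,
    method: str = "timestamps",
    hold_window: float = 2.0,
    hold_variance_threshold: float = 0.5,
) -> cm.SessionData:
    """Resample the ground truth onto the surrogate timeline.

    ``"timestamps"`` trusts the shared clock and linearly interpolates
    the ground truth onto surrogate timestamps inside the overlapping
    support (never extrapolating).  ``"breathholds"`` first estimates a
    constant clock offset by aligning the end of the leading breath-hold
    detected in each stream, applies it to the ground-truth timestamps,
    then proceeds as above; samples inside detected hold windows are
    flagged out of model fitting (not deleted).
    """
    ts = pair.surrogate.timestamps
    xs = pair.surrogate.values_mm
    tg = pair.ground_truth.timestamps
    yg = pair.ground_truth.si_mm
    offset = 0.0
    holds_s: list[tuple[float, float]] = []
    if method == "breathholds":
        end_s, holds_s = _leading_hold_end(ts, xs, hold_window, hold_variance_threshold)
        end_g, _ = _leading_hold_end(tg, yg, hold_window, hold_variance_threshold)
        offset = end_s - end_g
        tg = tg + offset
    elif method != "timestamps":
        raise InvalidArgumentError(f"unknown synchronization method {method!r}")
    t0, t1 = max(ts[0], tg[0]), min(ts[-1], tg[-1])
    if t0 >= t1:
        raise SynchronizationError("streams have no overlapping time support")
    keep = (ts >= t0) & (ts <= t1)
    t = ts[keep]
    x = xs[keep]
    y = np.interp(t, tg, yg)
    include = np.ones(t.size, dtype=bool)
    if method == "breathholds":
        for h0, h1 in holds_s:
            include &= ~((t >= h0) & (t <= h1))
    session = cm.SessionData(
        session_id=pair.session_id, timestamps=t, x=x, y=y, include=include
    )
    session.offset_s = offset  # alignment metadata
    return session


# ---------------------------------------------------------------------------
# experiment configurations


@dataclass
class PhantomConfig:
    """Robotic-phantom run: periodic motion, EM-style ground truth at 40 Hz."""

    amplitude_si: float = 30.0
    amplitude_ap: float = 10.0
    frequency: float = 0.25
    waveform: str = "raised-cosine-power"
    duration: float = 60.0
    surrogate_rate: float = 30.0
    groundtruth_rate: float = 40.0
    surrogate_noise_sd: float = 1.0  # mm, on the surrogate channel
    degree: int = 3
    train_fraction: float = 0.7
    patch: sim.SurfacePatchModel = field(
        default_factory=lambda: sim.SurfacePatchModel(depth_noise_sd=0.0)
    )
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PhantomConfig":
        return _config_from_json(cls, path)


@dataclass
class ClinicalConfig:
    """Multi-subject, multi-session run with ultrasound-style ground truth."""

    n_subjects: int = 6
    protocol: sim.ProtocolSpec = field(default_factory=sim.ProtocolSpec)
    amplitude_si_range: tuple[float, float] = (20.0, 50.0)
    ap_ratio: float = 1.0 / 3.0  # AP amplitude as a fraction of SI (phantom ratio)
    session_scales: tuple[float, ...] = (1.0, 0.9, 1.1)
    baseline_shift_max: float = 3.0  # mm, uniform per session
    frequency_jitter: float = 0.02
    waveform: str = "raised-cosine-power"
    surrogate_noise_sd: float = 1.0  # mm
    degree: int = 3
    train_fraction: float = 0.7
    sync_method: str = "breathholds"
    patch: sim.SurfacePatchModel = field(
        default_factory=lambda: sim.SurfacePatchModel(depth_noise_sd=0.0)
    )
    mask_image_size: tuple[int, int] = (64, 320)
    mask_pixel_spacing: float = 0.027
    mask_rest_col: int = 40
    filter_cfg: ut.FilterConfig = field(default_factory=ut.FilterConfig)
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "ClinicalConfig":
        return _config_from_json(cls, path)


def _config_from_json(cls, path):
    """Build a config dataclass from a JSON file, rejecting unknown keys."""
    raw = json.loads(Path(path).read_text())
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise InvalidArgumentError("config must state an explicit seed")
    if "patch" in raw:
        raw["patch"] = sim.SurfacePatchModel(**raw["patch"])
    if "protocol" in raw:
        raw["protocol"] = sim.ProtocolSpec(**raw["protocol"])
    if "filter_cfg" in raw:
        raw["filter_cfg"] = ut.FilterConfig(**raw["filter_cfg"])
    for key in ("amplitude_si_range", "session_scales", "mask_image_size"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return cls(**raw)


def _write_log(out_dir, record: dict):
    if out_dir is None:
        return
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = dict(record, wallclock=time.strftime("%Y-%m-%dT%H:%M:%S"))
    with open(out_dir / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(record, default=str) + "\n")


# ---------------------------------------------------------------------------
# experiments


def phantom_session_data(config: PhantomConfig, axis: str = "SI") -> cm.SessionData:
    """Simulate the phantom and return the synchronized (x, y) pair."""
    params = sim.BreathingParams(
        amplitude_si=config.amplitude_si,
        amplitude_ap=config.amplitude_ap,
        frequency=config.frequency,
        waveform=config.waveform,
        seed=config.seed,
    )
    trace = sim.simulate_breathing_trace(params, config.duration, config.groundtruth_rate)
    clouds = sim.simulate_surface_sequence(
        trace, config.patch, config.surrogate_rate, seed=config.seed
    )
    reference = sg.select_reference_cloud(clouds)
    series = sg.compute_surrogate_series(clouds, reference)
    if config.surrogate_noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        series.values_mm = series.values_mm + rng.normal(
            0.0, config.surrogate_noise_sd, len(series)
        )
    gt = DisplacementTrace(
        timestamps=trace.timestamps,
        si_mm=trace.channel(axis),
        axis_label=axis,
    )
    return synchronize(StreamPair(series, gt), method="timestamps")


def run_phantom_experiment(config: PhantomConfig, out_dir=None) -> dict:
    """Specific-regime model per motion axis; returns a two-axis report."""
    report = {"config": dataclasses.asdict(config), "axes": {}}
    for axis in ("SI", "AP"):
        session = phantom_session_data(config, axis)
        res = cm.run_specific_model(
            session, degree=config.degree, train_fraction=config.train_fraction
        )
        report["axes"][axis] = res.to_dict()
    _write_log(out_dir, {"experiment": "phantom", "config": report["config"]})
    return report


def simulate_clinical_subject(
    config: ClinicalConfig, subject_index: int
) -> tuple[list[cm.SessionData], dict]:
    """Simulate one subject and run the full measurement chain.

    Surface clouds -> surrogate series (+ sensor noise); mask sequence
    -> edge tracking -> ground-truth trace; streams synchronized via the
    configured method.  Returns the per-session (x, y) data and the
    subject's generation parameters.
    """
    subject_seed = config.seed + 1000 * (subject_index + 1)
    rng = np.random.default_rng(subject_seed)
    lo, hi = config.amplitude_si_range
    a_si = float(rng.uniform(lo, hi))
    a_ap = a_si * config.ap_ratio
    shifts = rng.uniform(-config.baseline_shift_max, config.baseline_shift_max,
                         len(config.session_scales))
    params = sim.BreathingParams(
        amplitude_si=a_si,
        amplitude_ap=a_ap,
        frequency=0.25,
        waveform=config.waveform,
        seed=subject_seed,
    )
    variability = [
        sim.SessionVariability(
            amplitude_scale=s, baseline_shift=float(b),
            frequency_jitter=config.frequency_jitter,
        )
        for s, b in zip(config.session_scales, shifts)
    ]
    protocol = dataclasses.replace(
        config.protocol, n_sessions=len(config.session_scales)
    )
    raws = sim.simulate_session_set(
        params, protocol, variability,
        patch=config.patch,
        mask_image_size=config.mask_image_size,
        mask_pixel_spacing=config.mask_pixel_spacing,
        mask_rest_col=config.mask_rest_col,
    )
    rows, cols = config.mask_image_size
    roi = ut.RoiBox(rows // 8 + 2, rows - rows // 8 - 2, 1, cols)
    sessions = []
    for raw in raws:
        reference = sg.select_reference_cloud(raw.clouds)
        series = sg.compute_surrogate_series(raw.clouds, reference)
        if config.surrogate_noise_sd > 0:
            srng = np.random.default_rng(raw.seed + 500_000)
            series.values_mm = series.values_mm + srng.normal(
                0.0, config.surrogate_noise_sd, len(series)
            )
        edges = [ut.extract_edge(m) for m in raw.masks]
        gt = ut.track_displacement(
            edges, roi,
            pixel_spacing=config.mask_pixel_spacing,
            filter_cfg=config.filter_cfg,
            timestamps=raw.trace_groundtruth_rate.timestamps,
        )
        pair = StreamPair(series, gt, session_id=raw.session_id)
        sessions.append(synchronize(pair, method=config.sync_method))
    meta = {
        "subject_seed": subject_seed,
        "amplitude_si_mm": a_si,
        "amplitude_ap_mm": a_ap,
        "baseline_shifts_mm": [float(b) for b in shifts],
    }
    return sessions, meta


def run_clinical_experiment(config: ClinicalConfig, out_dir=None) -> dict:
    """All three regimes per subject plus equal-weight overall rows."""
    if len(config.session_scales) < 2:
        raise InvalidArgumentError("clinical experiment needs >= 2 sessions")
    subjects = {}
    for i in range(config.n_subjects):
        sessions, meta = simulate_clinical_subject(config, i)
        regimes = {
            "single": cm.run_single_model(sessions, degree=config.degree),
            "specific": cm.run_specific_models(
                sessions, degree=config.degree, train_fraction=config.train_fraction
            ),
            "combined": cm.run_combined_model(
                sessions, degree=config.degree, train_fraction=config.train_fraction
            ),
        }
        subjects[i + 1] = {
            "meta": meta,
            "regimes": {k: v.to_dict() for k, v in regimes.items()},
        }
    overall = {}
    for regime in ("single", "specific", "combined"):
        block = {}
        for part in ("train", "test"):
            for metric in ("mae_mm", "r2_pct"):
                vals = np.array(
                    [subjects[s]["regimes"][regime][part][metric] for s in subjects]
                )
                sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
                block[f"{part}_{metric}"] = {"mean": float(np.mean(vals)), "sd": sd}
        overall[regime] = block
    report = {
        "config": dataclasses.asdict(config),
        "subjects": subjects,
        "overall": overall,
    }
    _write_log(out_dir, {"experiment": "clinical", "config": report["config"]})
    return report


# ---------------------------------------------------------------------------
# cohort motion tables


def overall_from_session_means(session_means) -> tuple[float, float]:
    """Cohort-level amplitude: mean and sample sd (ddof 1) of session means."""
    vals = np.asarray(session_means, dtype=float)
    if vals.size == 0:
        raise InvalidArgumentError("no session means")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd


def summarize_cohort(traces: dict) -> dict:
    """Per-session amplitude summaries plus the cohort-level row.

    ``traces`` maps ``(subject_id, session_id)`` to a
    :class:`DisplacementTrace`.  Each session is summarised by the mean
    +/- sd of its per-cycle peak-to-trough amplitudes; the overall row is
    the mean and sample sd over the per-session means.
    """
    if not traces:
        raise InvalidArgumentError("no traces")
    rows = []
    for (subject, session), trace in sorted(traces.items()):
        summary = ut.summarize_displacement(trace)
        rows.append(
            {
                "subject": subject,
                "session": session,
                "amplitude_mean_mm": summary["amplitude_mean_mm"],
                "amplitude_sd_mm": summary["amplitude_sd_mm"],
                "n_cycles": summary["n_cycles"],
            }
        )
    mean, sd = overall_from_session_means([r["amplitude_mean_mm"] for r in rows])
    return {"sessions": rows, "overall_mean_mm": mean, "overall_sd_mm": sd}
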