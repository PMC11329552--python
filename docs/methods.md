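# Methods

## Surrogate definition

The surrogate is the *directed, unsigned* mean nearest-neighbour
distance from the current surface cloud to the reference cloud
(current → reference), in mm. The reference is the maximum-inhalation
frame, selected as the frame whose mean coordinate along the configured
height axis is extremal in the configured inhalation direction
(`extreme-height` strategy; ties go to the earliest frame, and an
explicit `index` strategy exists for manual selection). Because the
reference sits at one extreme of the breathing cycle, every other phase
lies on one side of it and the unsigned distance is monotone in the
breathing phase; a signed variant (nearest-neighbour offset projected on
the height axis) is available behind a flag for sensitivity analysis but
is not the default, since unsigned distance is robust to lateral
sampling mismatch between clouds. Nearest neighbours use a k-d tree
built once per reference; unit tests pin the values to an exhaustive
O(N·M) search.

Height axis and inhalation sign are configuration, never inferred: a
camera above a supine subject sees inhalation as a *decrease* in
distance, a world-frame simulation as an increase.

## Correspondence model

Ordinary least squares on the polynomial design. The solve runs on a
centred/scaled copy of x (the domain mapping of
`numpy.polynomial.Polynomial.fit`, i.e. orthogonal-decomposition
semantics) and coefficients are mapped back to the original scale, so
reported β are in mm·mm⁻ᵏ. The polynomial degree defaults to 3 —
low enough not to oscillate on a scalar surrogate, high enough to absorb
the mild geometric nonlinearity between surface distance and internal
displacement; `select_degree` (held-out MAE over degrees 1–5) exists but
is off by default. A fit requires at least degree + 1 samples and
degree + 1 distinct x values; anything less raises a degenerate-fit
error naming the degree.

The 70/30 split is chronologically contiguous by default because
breathing samples are strongly serially correlated — a random split
would leak near-duplicate neighbours of training samples into the test
set and flatter the model. A seeded random split is available
(`mode="random"`, seed mandatory); with it, the specific regime can be
repeated `n_repeats` times and reported mean ± sd.

R² is reported in percent and may be negative for out-of-session
predictions; it is reported as-is. A zero-variance test target makes R²
undefined: it is returned as NaN with a warning while MAE is still
computed.

## Ground truth from mask sequences

Post-processing of a binary mask keeps the largest 8-connected
component (ties resolved to the component whose first pixel comes
earliest in row-major order), fills interior holes, and applies a
closing with a disk of radius 2 px (radius 0 disables it). Edges are
foreground pixels with a 4-connected background neighbour, with the
image border counting as background. The tracked coordinate is the
*mean* column of edge pixels inside the ROI (median behind a flag);
displacement is `(col − col₀) · pixel_spacing` with the reference
scanner's 0.027 cm/px, positive towards increasing column. The 1-D
signal is then smoothed with a zero-phase (forward–backward)
second-order Butterworth low-pass at 1 Hz — above the 0.1–0.5 Hz
breathing band, below pixel-quantisation chatter; the filter is skipped
when the cutoff reaches Nyquist. Tracking gaps (no edge pixel in the
ROI) raise an error naming the frame, or are linearly interpolated when
at most `max_gap` consecutive frames are affected.

Dice is `100·2|A∩B|/(|A|+|B|)`. The Hausdorff distance is the symmetric
max-min Euclidean distance between edge sets, computed in pixels and
converted with the isotropic spacing (px · spacing · 10 mm); the ROI
variant restricts *both* sets to the box first. Segmentation evaluation
samples 20 frames without replacement (seeded) and reports mean ± sd;
shorter sequences use all frames and record a warning.

Per-cycle amplitude summaries detect peaks and troughs with a prominence
threshold of 25 % of the global range (plateau-tolerant), treat the
trace ends as extrema so half-cycles at the boundaries count, and report
mean ± sd (ddof 1) of adjacent peak–trough differences.

## Synchronization

Ground truth is resampled onto the surrogate timeline (the stream that
would be resampled least: 30 Hz vs. 15 Hz ultrasound; 40 Hz EM data is
effectively decimated onto it), by linear interpolation inside the
overlapping support only — never extrapolating.

Breath-holds are detected as windows whose centred 2-s rolling sample
variance falls below 0.5 mm² after a light moving-average pre-smooth.
For offset estimation the raw hold-window edge is *not* used: its lag
depends on each stream's amplitude and noise and would bias the offset.
Instead the hold end is the sub-sample time at which the smoothed signal
first departs from the hold level by 10 % of the stream's full range — a
phase point shared by two streams that are affine images of the same
breathing waveform, so the per-stream bias cancels in the difference.
Samples inside detected hold windows are flagged out of model fitting
but kept in the session record.

## Simulator

The simulator emulates the statistical structure the pipeline assumes,
not the physics of any sensor.

* **Waveform.** Default `raised-cosine-power`: w(φ) = sin⁴(πφ), φ the
  phase in cycles — longer exhale plateaus than a sinusoid, trough at
  φ = 0, normalised to [0, 1] so the configured amplitude is exactly the
  peak-to-trough excursion. A pure sinusoid is selectable. The phantom
  defaults are 30 mm SI / 10 mm AP at 0.25 Hz; SI and AP move in phase
  by default with the phase offset exposed as a parameter, since the
  actuator phase relation of the physical phantom is not constrained.
* **Sessions.** Each session is hold – breathing – hold, with holds
  modelled at end-exhale (flat at the trough). The breathing segment's
  cycle count is snapped to an integer so the segment starts and ends at
  the trough, continuous with the holds (the effective in-session
  frequency can differ from nominal by up to half a cycle per segment).
  Per-session variability: amplitude scale, baseline shift (mm), and
  fractional per-cycle period jitter realised by perturbing cycle
  lengths and rescaling them to fill the segment. Session k uses seed
  `master_seed + k`.
* **Surface.** A 30 cm square grid (1.5 cm spacing) with a smooth
  Gaussian bump of 2 cm relief — the scale of abdominal surface relief
  over such a window — elevated rigidly by `coupling` (default 1 mm of
  surface per mm of internal AP displacement), with optional per-point
  Gaussian depth noise (default 1 mm sd, consumer depth-camera scale;
  the reference experiments instead inject 1 mm noise directly into the
  surrogate channel so the noise level on the regressor is explicit).
* **Masks.** A filled region whose right edge column follows
  `round(rest + profile(row) + SI(t)/spacing)`, single-component and
  hole-free by construction; the default edge profile is a gentle
  parabolic bow so the edge is not a straight line.
* **Clinical analog.** Subject SI amplitudes are drawn uniformly from
  20–50 mm (the range spanned by published per-session liver
  displacements); AP amplitude is SI/3, the phantom's 30:10 ratio;
  session scales default to (1.0, 0.9, 1.1) with baseline shifts uniform
  within ±3 mm and 2 % period jitter.

What the simulator does **not** reproduce: surface deformation beyond a
rigid coupled elevation, camera noise structure (quantisation, edge
dropout), ultrasound speckle or segmentation failures (masks are clean
by construction), cardiac motion, and surrogate–target phase lag (none
is injected, consistent with the modelling assumption of negligible
liver phase shift). Passing tests therefore demonstrate the
correctness and internal consistency of the estimation chain under the
assumed signal structure — not clinical performance on real recordings,
where segmentation quality and physiological variability dominate.

## Numerical choices and problem sizes

* Reference-frame ties, component-size ties and split boundaries all
  have deterministic documented tie-breaks; fixed seeds make every
  report bit-identical across runs.
* Traces are float64 throughout; on-disk PLY is ASCII float32
  (≈ 0.1 µm at metre scale, far below sensor noise).
* The reference experiments use 60 s sessions (30 Hz surrogate, 15 Hz
  masks, 40 Hz EM) — enough for ~12 breathing cycles per session and
  stable OLS estimates; the test suite uses shorter sessions and coarser
  surface grids for the same chain, sizes chosen to keep each property
  detectable.
* `detect_breathholds` thresholds (2 s window, 0.5 mm² variance) assume
  millimetre-scale breathing signals; signals in other units need the
  threshold rescaled.

## Known limitations

* The correspondence model is memoryless: hysteresis between surface and
  organ motion (inhale/exhale loop splitting) would need a phase-aware
  regressor and is not modelled, in the generator or the estimator.
* Edge tracking summarises the ROI edge by one scalar; rotations or
  deformations of the liver boundary inside the ROI alias into apparent
  translation.
* Breath-hold alignment assumes both streams contain a detectable
  leading hold; recordings without one must use timestamp
  synchronization.
* The mask-based ground truth quantises displacement to 0.27 mm per
  pixel before filtering; sub-pixel tracking is not attempted.
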