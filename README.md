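# rimotion

Estimation of liver respiratory-induced motion (RIM) from an external
surface surrogate, for researchers working on motion management in
percutaneous liver interventions and image-guided therapy.

During free breathing the liver translates mainly along the
superior-inferior (SI) axis by a few centimetres. Inserting a needle or
planning a beam therefore needs a real-time estimate of the internal
displacement, but imaging the target continuously is impractical. A
*surrogate* signal — here, the motion of the abdominal surface as seen by
a depth camera — can be mapped to the internal displacement through a
*correspondence model* trained against a ground-truth measurement
(an electromagnetic sensor in a robotic phantom, or liver edges tracked
in segmented ultrasound for human sessions).

## Model

The surrogate is the mean closest-point distance from each surface point
cloud to a reference cloud captured at maximum inhalation:

    x(t) = (1/N) Σᵢ minⱼ ‖pᵢ(t) − rⱼ‖₂   [mm]

The internal displacement y (mm) is modelled as a degree-n polynomial in
x, fitted by ordinary least squares:

    y(β) = β₀ + β₁x + … + βₙxⁿ,   β̂ = argmin Σᵢ (yᵢ − y(β; xᵢ))²

Three training regimes probe intra- vs. inter-fraction variability over
the sessions S₁…S₃ of one subject:

| regime   | trained on                   | tested on                       |
|----------|------------------------------|---------------------------------|
| single   | all of S₁                    | each remaining session          |
| specific | first 70 % of one session    | that session's held-out 30 %    |
| combined | pooled 70 % of every session | each session's held-out 30 %    |

Performance is reported as mean absolute error (MAE, mm) and coefficient
of determination (R², %).

The package also contains the ground-truth chain for mask-based
recordings (largest-component/hole-filling post-processing, 4-connected
edge extraction, ROI-restricted x-axis edge tracking at 0.027 cm/px,
Dice and Hausdorff evaluation) and a simulator of both validation
set-ups — a robotic phantom (30 mm SI / 10 mm AP peak-to-trough at
0.25 Hz) and multi-session human-style recordings (1-min sessions
bounded by breath-holds, with inter-session amplitude and baseline
drift) — so the entire pipeline runs end-to-end without any data
downloads.

## Worked example

```sh
$ rimotion phantom-demo --seed 0
SI: train MAE 1.82 mm, R2 95.0 % | test MAE 1.84 mm, R2 94.6 %
AP: train MAE 0.61 mm, R2 95.0 % | test MAE 0.61 mm, R2 94.6 %
```

A phantom session (60 s at 30 Hz, 1 mm Gaussian noise on the surrogate)
is simulated, the surrogate computed from the surface clouds, streams
synchronized by timestamps, and one degree-3 specific model fitted per
motion axis on the first 70 % of the session. Held-out errors below
2 mm with R² near 95 % mean the surrogate explains almost all of the
internal motion; the AP axis has a smaller MAE simply because its
10 mm excursion is a third of the SI one.

```sh
$ rimotion clinical-demo --seed 0 --subjects 3
  single: test MAE 3.17 +/- 0.21 mm, R2 89.6 +/- 0.2 %
specific: test MAE 1.98 +/- 0.02 mm, R2 95.5 +/- 0.5 %
combined: test MAE 2.76 +/- 0.09 mm, R2 91.6 +/- 0.3 %
```

Three subjects, three drifting sessions each, full chain (clouds →
surrogate; masks → edge tracking → ground truth; breath-hold
synchronization; all three regimes). The ordering — single worst,
specific best, combined between — is the expected signature of
inter-session drift: a model trained on an earlier session inherits that
session's amplitude and baseline.

The same functionality is available as a library:

```python
from rimotion import pipeline as pl
report = pl.run_clinical_experiment(pl.ClinicalConfig(seed=0))
print(report["overall"]["specific"]["test_mae_mm"])
```

The CLI also exposes the individual stages (`simulate`, `surrogate`,
`track`, `sync`, `fit`, `report`) operating on the on-disk formats
(ASCII PLY + `frames.csv`, CSV traces, PNG masks, JSON configs/reports).

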