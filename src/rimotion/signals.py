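"""Timestamped displacement traces shared across modules.

A :class:`DisplacementTrace` holds the internal liver displacement over
time.  The superior-inferior (SI) channel is always present; the
anterior-posterior (AP) channel exists for phantom-style recordings where
both axes are actuated.  Displacements are stored in millimetres; a
centimetre view is provided because ultrasound pixel spacings are quoted
in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError


@dataclass
class DisplacementTrace:
    """1-D (or 2-axis) internal displacement sampled over time.

    Parameters
    ----------
    timestamps
        Sample times in seconds, strictly increasing.
    si_mm
        Superior-inferior displacement in mm, same length as ``timestamps``.
    ap_mm
        Optional anterior-posterior displacement in mm.
    axis_label
        Name of the primary axis (default ``"SI"``).
    """

    timestamps: np.ndarray
    si_mm: np.ndarray
    ap_mm: np.ndarray | None = None
    axis_label: str = "SI"

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.si_mm = np.asarray(self.si_mm, dtype=float)
        if self.ap_mm is not None:
            self.ap_mm = np.asarray(self.ap_mm, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.size == 0:
            raise InvalidArgumentError("trace needs a non-empty 1-D timestamp vector")
        if self.si_mm.shape != self.timestamps.shape:
            raise InvalidArgumentError("si_mm and timestamps must have equal length")
        if self.ap_mm is not None and self.ap_mm.shape != self.timestamps.shape:
            raise InvalidArgumentError("ap_mm and timestamps must have equal length")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.timestamps)) and np.all(np.isfinite(self.si_mm))):
            raise InvalidArgumentError("trace values must be finite")

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def si_cm(self) -> np.ndarray:
        return self.si_mm / 10.0

    @property
    def rate(self) -> float:
        """Mean sampling rate in Hz."""
        if len(self) < 2:
            raise InvalidArgumentError("rate undefined for a single-sample trace")
        return (len(self) - 1) / (self.timestamps[-1] - self.timestamps[0])

    def channel(self, axis: str) -> np.ndarray:
        axis = axis.upper()
        if axis == "SI":
            return self.si_mm
        if axis == "AP":
            if self.ap_mm is None:
                raise InvalidArgumentError("trace has no AP channel")
            return self.ap_mm
        raise InvalidArgumentError(f"unknown axis {axis!r}")
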