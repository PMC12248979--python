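"""Binocular gaze trace container.

Positions are in degrees of visual angle relative to the fixation point at
(0, 0); time is in milliseconds from stimulus onset.  Samples inside blinks
are marked invalid and their positions are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GazeTrace:
    """One trial's binocular gaze recording.

    Attributes
    ----------
    time_ms : (n,) float array of sample timestamps, uniformly spaced.
    left, right : (n, 2) arrays of horizontal/vertical position in deg.
    valid_left, valid_right : (n,) boolean validity flags (False in blinks).
    sampling_rate : samples per second.
    """

    time_ms: np.ndarray
    left: np.ndarray
    right: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray
    sampling_rate: float
    participant: str | None = None
    trial: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_ms)
        for name in ("left", "right"):
            arr = getattr(self, name)
            if arr.shape != (n, 2):
                raise ValueError(f"{name} must have shape (n, 2), got {arr.shape}")
        for name in ("valid_left", "valid_right"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape (n,), got {arr.shape}")
        if n >= 2:
            dt = np.diff(self.time_ms)
            expected = 1000.0 / self.sampling_rate
            if not np.allclose(dt, expected, rtol=1e-6, atol=1e-6):
                raise ValueError("timestamps are not uniformly spaced at the stated rate")

    @property
    def n_samples(self) -> int:
        return len(self.time_ms)

    @property
    def duration_s(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(self.time_ms[-1] - self.time_ms[0]) / 1000.0

    @property
    def valid(self) -> np.ndarray:
        """Samples valid in both eyes."""
        return self.valid_left & self.valid_right

    def binocular(self) -> np.ndarray:
        """Mean of the two eyes' positions, (n, 2)."""
        return 0.5 * (self.left + self.right)

    def blink_intervals(self) -> list[tuple[float, float]]:
        """Contiguous invalid runs (either eye) as (onset_ms, offset_ms)."""
        invalid = ~self.valid
        if not invalid.any():
            return []
        edges = np.diff(invalid.astype(int))
        starts = list(np.where(edges == 1)[0] + 1)
        ends = list(np.where(edges == -1)[0])
        if invalid[0]:
            starts.insert(0, 0)
        if invalid[-1]:
            ends.append(len(invalid) - 1)
        return [(float(self.time_ms[s]), float(self.time_ms[e])) for s, e in zip(starts, ends)]
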