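"""Trial-level oculomotor metrics.

Computes, per trial: mean ocular drift via the retinal-slip grid method,
exclusion status under the study's rules, microsaccade summaries, and the
immobilization time (interval from the last microsaccade to the report).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .detect import Microsaccade
from .gaze import GazeTrace


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    SHORT_TRIAL = "short_trial"
    GAZE_DISPLACEMENT = "gaze_displacement"
    PERI_PRESS_BLINK = "peri_press_blink"
    PERI_PRESS_SACCADE = "peri_press_saccade"


@dataclass
class TrialMetrics:
    """Derived quantities for one trial."""

    trial_id: str
    participant: str
    ft_s: float
    log_ft: float
    ms_presence: bool
    ms_count: int
    ms_rate: float  # Hz, count / FT
    num_blinks: int
    mean_drift: float  # deg/s; NaN when no valid segment
    immobilization_ms: float  # NaN when undefined
    excluded: bool
    exclusion_reason: ExclusionReason
    last_ms_amplitude: float = float("nan")  # deg; covariate of the immobilization model


def retinal_slip(
    trace: GazeTrace,
    events: list[Microsaccade],
    grid_deg: float = 0.01,
    segment_ms: float = 50.0,
    pad_ms: float = 10.0,
) -> float:
    """Mean ocular drift speed from grid traversal of the binocular path.

    The trial is cut into ``segment_ms`` segments.  A segment is valid when it
    contains no invalid sample and no sample within ``pad_ms`` of a
    microsaccade.  Within a valid segment, the number of distinct
    ``grid_deg``-square cells entered by the binocular mean gaze path is
    converted to a speed: ``(count - 1) * grid_deg / segment_duration``.
    Returns the mean over valid segments, or NaN if none exists (a stationary
    eye yields exactly 0).
    """
    fs = trace.sampling_rate
    seg = int(round(segment_ms * fs / 1000.0))
    if seg < 2:
        raise ValueError("segment must span at least 2 samples")
    pos = trace.binocular()
    valid = trace.valid.copy()
    t = trace.time_ms
    for ev in events:
        near = (t >= ev.onset_ms - pad_ms) & (t <= ev.offset_ms + pad_ms)
        valid &= ~near

    speeds = []
    dur_s = (seg - 1) / fs  # time spanned by the segment's samples
    for s in range(0, trace.n_samples - seg + 1, seg):
        sl = slice(s, s + seg)
        if not valid[sl].all():
            continue
        cells = np.floor(pos[sl] / grid_deg).astype(np.int64)
        count = len({(int(a), int(b)) for a, b in cells})
        speeds.append((count - 1) * grid_deg / dur_s)
    return float(np.mean(speeds)) if speeds else float("nan")


def apply_exclusions(
    ft_s: float,
    trace: GazeTrace,
    large_saccades: list[Microsaccade],
    blinks: list[tuple[float, float]],
    press_ms: float | None = None,
    min_ft_s: float = 2.0,
    max_displacement_deg: float = 1.0,
    peri_press_ms: float = 300.0,
) -> tuple[bool, ExclusionReason]:
    """Evaluate the trial exclusion rules; returns ``(kept, reason)``.

    Rules, in fixed precedence order: FT below ``min_ft_s``; median binocular
    gaze displacement from the fixation point above ``max_displacement_deg``;
    a blink or a large saccade within ``peri_press_ms`` before the press.
    """
    if trace is None:
        raise ValueError("trace required to evaluate exclusions")
    if ft_s < min_ft_s:
        return False, ExclusionReason.SHORT_TRIAL
    pos = trace.binocular()[trace.valid]
    if len(pos):
        disp = np.hypot(pos[:, 0], pos[:, 1])
        if np.median(disp) > max_displacement_deg:
            return False, ExclusionReason.GAZE_DISPLACEMENT
    press = ft_s * 1000.0 if press_ms is None else press_ms
    w0 = press - peri_press_ms
    for on, off in blinks:
        if off >= w0 and on <= press:
            return False, ExclusionReason.PERI_PRESS_BLINK
    for ev in large_saccades:
        if ev.offset_ms >= w0 and ev.onset_ms <= press:
            return False, ExclusionReason.PERI_PRESS_SACCADE
    return True, ExclusionReason.NONE


def immobilization_time(
    press_ms: float,
    events: list[Microsaccade],
    min_interval_ms: float = 300.0,
) -> float | None:
    """Press time minus the offset of the last microsaccade, in ms.

    Defined only when the last microsaccade ended more than
    ``min_interval_ms`` before the press (later events are likely tied to
    motor execution, not perception); ``None`` when undefined or when the
    trial has no events.
    """
    if not events:
        return None
    last = max(ev.offset_ms for ev in events)
    interval = press_ms - last
    if interval <= min_interval_ms:
        return None
    return float(interval)


def summarize_trial(
    trial_id: str,
    participant: str,
    ft_s: float,
    trace: GazeTrace,
    events: list[Microsaccade],
    large_saccades: list[Microsaccade],
    blinks: list[tuple[float, float]] | None = None,
) -> TrialMetrics:
    """Assemble all per-trial metrics; exclusions are evaluated here too."""
    blinks = trace.blink_intervals() if blinks is None else blinks
    kept, reason = apply_exclusions(ft_s, trace, large_saccades, blinks)
    press_ms = ft_s * 1000.0
    immo = immobilization_time(press_ms, events)
    drift = retinal_slip(trace, events + large_saccades)
    return TrialMetrics(
        trial_id=trial_id,
        participant=participant,
        ft_s=ft_s,
        log_ft=math.log(ft_s) if ft_s > 0 else float("nan"),
        ms_presence=len(events) > 0,
        ms_count=len(events),
        ms_rate=len(events) / ft_s if ft_s > 0 else float("nan"),
        num_blinks=len(blinks),
        mean_drift=drift,
        immobilization_ms=float("nan") if immo is None else immo,
        excluded=not kept,
        exclusion_reason=reason,
        last_ms_amplitude=(max(events, key=lambda ev: ev.offset_ms).amplitude_deg
                           if events else float("nan")),
    )
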