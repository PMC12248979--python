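"""Binocular velocity-threshold microsaccade detection.

The detector follows the velocity-threshold family standard in fixational
eye-movement research: gaze position is converted to velocity with a sliding
regression window, a robust per-axis noise scale sets an elliptic velocity
threshold, and candidate events are runs of samples that exceed the threshold
simultaneously in both eyes.  Candidate events are then merged across short
gaps and filtered on duration, direction stability, amplitude and proximity
to blinks.  Events larger than the microsaccade amplitude ceiling (or with a
sustained high speed) are returned separately as large saccades so that
exclusion logic can use them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

ARCMIN_PER_DEG = 60.0


@dataclass
class DetectionParams:
    """Tunable constants of the detection algorithm.

    velocity_window_ms : span of the sliding regression window (odd samples).
    noise_multiplier : lambda; threshold = lambda x robust noise SD per axis.
    min_duration_samples : minimum suprathreshold run length.
    merge_gap_ms : events separated by less than this are merged.
    max_direction_change : allowed movement-direction change, deg per ms.
    amp_min_arcmin / amp_max_deg : microsaccade amplitude window; below is
        drift/noise, above is a large saccade.
    blink_pad_ms : exclusion margin around invalid (blink) samples.
    large_saccade_velocity : sustained speed (deg/s) that marks a large saccade.
    min_direction_speed : speed floor (deg/s) below which movement direction
        is treated as undefined in the direction-change test.
    """

    velocity_window_ms: float = 31.0
    noise_multiplier: float = 5.0
    min_duration_samples: int = 8
    merge_gap_ms: float = 12.0
    max_direction_change: float = 15.0
    amp_min_arcmin: float = 3.0
    amp_max_deg: float = 2.0
    blink_pad_ms: float = 150.0
    large_saccade_velocity: float = 30.0
    min_direction_speed: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_multiplier <= 0:
            raise ValueError("noise_multiplier must be positive")
        if self.amp_min_arcmin / ARCMIN_PER_DEG >= self.amp_max_deg:
            raise ValueError("amp_min must be below amp_max")
        if self.min_duration_samples < 1:
            raise ValueError("min_duration_samples must be >= 1")


@dataclass
class Microsaccade:
    """A detected (or injected ground-truth) ballistic event."""

    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    peak_velocity: float  # deg/s
    direction_deg: float  # atan2 of net displacement
    participant: str | None = None
    trial: int | None = None

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class VelocitySeries:
    """Per-eye 2-D velocity aligned to the trace timestamps (deg/s)."""

    time_ms: np.ndarray
    left: np.ndarray   # (n, 2)
    right: np.ndarray  # (n, 2)
    defined: np.ndarray  # (n,) True where velocity is defined for both eyes

    def binocular(self) -> np.ndarray:
        return 0.5 * (self.left + self.right)


def _window_samples(window_ms: float, fs: float) -> int:
    w = int(round(window_ms * fs / 1000.0))
    if w % 2 == 0:
        w += 1
    return w


def _dilate(mask: np.ndarray, k: int) -> np.ndarray:
    """Binary dilation of a 1-D boolean mask by k samples on each side."""
    if k <= 0 or not mask.any():
        return mask.copy()
    out = mask.copy()
    idx = np.where(mask)[0]
    for i in idx:
        out[max(0, i - k): i + k + 1] = True
    return out


def compute_velocity(trace, window_ms: float = 31.0, blink_pad_ms: float = 150.0) -> VelocitySeries:
    """Velocity as the slope of a centered least-squares line fit per window.

    Samples whose window touches an invalid sample, or that lie within
    ``blink_pad_ms`` of an invalid region, are marked undefined.  The trace
    must span at least one window.
    """
    fs = trace.sampling_rate
    w = _window_samples(window_ms, fs)
    if w < 3:
        raise ValueError("velocity window must span at least 3 samples")
    n = trace.n_samples
    if n < w:
        raise ValueError(f"trace of {n} samples is shorter than one {w}-sample window")
    k = w // 2
    i = np.arange(-k, k + 1, dtype=float)
    weights = i / np.sum(i**2) * fs  # slope of LS line, scaled to deg/s

    pad = int(round(blink_pad_ms * fs / 1000.0))
    invalid = _dilate(~(trace.valid_left & trace.valid_right), pad)

    defined = ~_dilate(invalid, k)
    defined[:k] = False
    defined[n - k:] = False

    def _slope(pos: np.ndarray) -> np.ndarray:
        x = np.where(invalid[:, None], 0.0, pos)
        out = np.empty_like(x)
        for ax in range(2):
            out[:, ax] = np.convolve(x[:, ax], weights[::-1], mode="same")
        out[~defined] = np.nan
        return out

    return VelocitySeries(
        time_ms=trace.time_ms,
        left=_slope(trace.left),
        right=_slope(trace.right),
        defined=defined,
    )


def estimate_threshold(vel: VelocitySeries, noise_multiplier: float = 5.0) -> np.ndarray:
    """Elliptic velocity thresholds, shape (2 eyes, 2 axes), in deg/s.

    The per-axis noise scale is the median-based robust SD
    sigma = sqrt(median(v^2) - median(v)^2); the threshold is
    ``noise_multiplier * sigma``.  Requires >= 100 defined samples; a zero
    noise scale on any axis signals an unusable (constant) trace.
    """
    d = vel.defined
    if int(d.sum()) < 100:
        raise ValueError("fewer than 100 defined velocity samples")
    eta = np.empty((2, 2))
    for e, v in enumerate((vel.left, vel.right)):
        for ax in range(2):
            vv = v[d, ax]
            sigma2 = np.median(vv**2) - np.median(vv) ** 2
            if sigma2 <= 0:
                raise ValueError("degenerate velocity distribution (zero noise scale)")
            eta[e, ax] = noise_multiplier * np.sqrt(sigma2)
    return eta


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, end) inclusive sample indices."""
    if not mask.any():
        return []
    m = mask.astype(int)
    edges = np.diff(m)
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


def merge_events(runs: list[tuple[int, int]], merge_gap_samples: float) -> list[tuple[int, int]]:
    """Merge runs separated by fewer than ``merge_gap_samples`` samples.

    Idempotent: merging already-merged output changes nothing.
    """
    if not runs:
        return []
    runs = sorted(runs)
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 < merge_gap_samples:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def detect_microsaccades(
    trace,
    params: DetectionParams | None = None,
    velocity: VelocitySeries | None = None,
) -> tuple[list[Microsaccade], list[Microsaccade]]:
    """Detect binocular microsaccades; returns (microsaccades, large_saccades).

    A sample is a candidate when the elliptic criterion
    ``(vx/eta_x)^2 + (vy/eta_y)^2 > 1`` holds in both eyes simultaneously.
    Candidate runs of at least ``min_duration_samples`` become events; events
    closer than ``merge_gap_ms`` are merged; events with an excessive
    direction change, or an amplitude below the microsaccade floor, are
    dropped; events above the amplitude ceiling or with sustained high speed
    are returned as large saccades.
    """
    params = params or DetectionParams()
    fs = trace.sampling_rate
    if velocity is None:
        velocity = compute_velocity(trace, params.velocity_window_ms, params.blink_pad_ms)
    eta = estimate_threshold(velocity, params.noise_multiplier)

    with np.errstate(invalid="ignore"):
        crit = np.ones(trace.n_samples, dtype=bool)
        for e, v in enumerate((velocity.left, velocity.right)):
            r2 = (v[:, 0] / eta[e, 0]) ** 2 + (v[:, 1] / eta[e, 1]) ** 2
            crit &= r2 > 1.0
    crit &= velocity.defined

    runs = [r for r in _runs(crit) if r[1] - r[0] + 1 >= params.min_duration_samples]
    runs = merge_events(runs, params.merge_gap_ms * fs / 1000.0)

    pos = trace.binocular()
    vm = velocity.binocular()
    speed = np.hypot(vm[:, 0], vm[:, 1])
    ms_per_sample = 1000.0 / fs

    micro: list[Microsaccade] = []
    large: list[Microsaccade] = []
    for s, e in runs:
        # direction-stability test on the binocular mean velocity
        ang = np.arctan2(vm[s:e + 1, 1], vm[s:e + 1, 0])
        sp = speed[s:e + 1]
        ok = np.isfinite(sp) & (sp >= params.min_direction_speed)
        stable = True
        for a, b in zip(range(len(ang) - 1), range(1, len(ang))):
            if not (ok[a] and ok[b]):
                continue
            dphi = np.degrees(np.abs(np.angle(np.exp(1j * (ang[b] - ang[a])))))
            if dphi / ms_per_sample > params.max_direction_change:
                stable = False
                break
        if not stable:
            continue

        seg = pos[s:e + 1]
        if not np.isfinite(seg).all():
            continue  # overlaps a blink
        span = seg.max(axis=0) - seg.min(axis=0)
        amplitude = float(np.hypot(span[0], span[1]))
        if amplitude < params.amp_min_arcmin / ARCMIN_PER_DEG:
            continue  # drift or noise
        net = seg[-1] - seg[0]
        event = Microsaccade(
            onset_ms=float(trace.time_ms[s]),
            offset_ms=float(trace.time_ms[e]),
            amplitude_deg=amplitude,
            peak_velocity=float(np.nanmax(sp)),
            direction_deg=float(np.degrees(np.arctan2(net[1], net[0]))),
            participant=trace.participant,
            trial=trace.trial,
        )
        sustained = float(np.median(sp[np.isfinite(sp)])) if np.isfinite(sp).any() else 0.0
        if amplitude > params.amp_max_deg or sustained > params.large_saccade_velocity:
            large.append(event)
        else:
            micro.append(event)
    return micro, large


def main_sequence(events: list[Microsaccade]) -> tuple[float, float]:
    """Slope and Pearson correlation of log peak velocity vs log amplitude.

    Requires at least 10 events.
    """
    if len(events) < 10:
        raise ValueError("main sequence requires at least 10 events")
    la = np.log([ev.amplitude_deg for ev in events])
    lv = np.log([ev.peak_velocity for ev in events])
    res = stats.linregress(la, lv)
    return float(res.slope), float(res.rvalue)
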