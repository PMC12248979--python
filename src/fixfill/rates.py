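"""Press-aligned microsaccade rate estimation with a causal kernel.

The rate at time t (relative to the report at t = 0) is the average, over
trials spanning t, of kernel-smoothed event onsets, using the one-sided
window standard in event-rate analysis: ``w(tau) = alpha^2 * tau * exp(-alpha
* tau)`` for ``tau >= 0``, truncated at the window length and renormalized to
unit integral, so the estimate at t depends only on events at or before t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class KernelParams:
    """Causal window: length in ms and inverse time constant per ms."""

    window_ms: float = 1001.0
    alpha: float = 1.0 / 100.0

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.alpha <= 0:
            raise ValueError("window_ms and alpha must be positive")


@dataclass
class RateCurve:
    """Press-aligned rate (Hz) on a 1-ms grid with per-time trial coverage."""

    time_ms: np.ndarray
    rate: np.ndarray
    n_trials: np.ndarray
    baseline_window_ms: tuple = (-5000.0, -3000.0)

    @property
    def baseline(self) -> float:
        """Mean rate over the baseline window before the press."""
        lo, hi = self.baseline_window_ms
        m = (self.time_ms >= lo) & (self.time_ms <= hi)
        if not m.any():
            raise ValueError("time grid does not cover the baseline window")
        return float(np.mean(self.rate[m]))


def causal_kernel(params: KernelParams | None = None) -> np.ndarray:
    """Kernel values on a 1-ms grid over [0, window_ms], unit integral."""
    params = params or KernelParams()
    tau = np.arange(0.0, params.window_ms + 1.0)
    w = params.alpha**2 * tau * np.exp(-params.alpha * tau)
    return w / w.sum()  # unit integral at 1-ms spacing


def causal_rate(
    onset_lists: list[np.ndarray],
    durations_ms: list[float],
    kernel: KernelParams | None = None,
    t_grid: np.ndarray | None = None,
) -> RateCurve:
    """Kernel-smoothed press-aligned rate pooled over trials.

    ``onset_lists`` holds, per trial, microsaccade onsets in ms relative to
    the press (so all onsets are <= 0); ``durations_ms`` the trial durations,
    so trial j spans [-duration_j, 0].  Only trials spanning a grid time
    contribute to the denominator there.  Trials with blinks or large
    saccades near the press should be removed by the caller beforehand.
    """
    if len(onset_lists) == 0:
        raise ValueError("no trials")
    if len(onset_lists) != len(durations_ms):
        raise ValueError("one duration per trial required")
    if t_grid is None:
        t_grid = np.arange(-float(np.max(durations_ms)), 1.0)
    k = causal_kernel(kernel)

    t0 = t_grid[0]
    ng = len(t_grid)
    hist = np.zeros(ng)
    coverage = np.zeros(ng)
    for onsets, dur in zip(onset_lists, durations_ms):
        lo = np.searchsorted(t_grid, -dur, side="left")
        hi = np.searchsorted(t_grid, 0.0, side="right")
        coverage[lo:hi] += 1
        for on in np.asarray(onsets, dtype=float):
            idx = int(round(on - t0))
            if 0 <= idx < ng:
                hist[idx] += 1
    smoothed = np.convolve(hist, k)[:ng]  # causal: kernel starts at lag 0
    rate = np.zeros(ng)
    nz = coverage > 0
    rate[nz] = 1000.0 * smoothed[nz] / coverage[nz]  # per-ms -> Hz
    return RateCurve(time_ms=t_grid.astype(float), rate=rate, n_trials=coverage)


def baseline_normalize(curves: dict[str, RateCurve]) -> tuple[dict[str, RateCurve], list[str]]:
    """Scale each participant's curve so its baseline equals the grand mean.

    Returns the normalized curves and the list of participants omitted
    because their baseline rate was zero (nothing to scale).
    """
    baselines = {p: c.baseline for p, c in curves.items()}
    usable = {p: b for p, b in baselines.items() if b > 0}
    omitted = sorted(set(curves) - set(usable))
    if not usable:
        raise ValueError("no participant has a positive baseline rate")
    grand = float(np.mean(list(usable.values())))
    out = {}
    for p, b in usable.items():
        c = curves[p]
        out[p] = RateCurve(
            time_ms=c.time_ms.copy(),
            rate=c.rate * (grand / b),
            n_trials=c.n_trials.copy(),
            baseline_window_ms=c.baseline_window_ms,
        )
    return out, omitted
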