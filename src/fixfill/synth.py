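"""Synthetic fixation experiments with known ground truth.

The generator emulates the structure of a perceptual filling-in experiment:
participants fixate while a colour boundary of a given contrast and
eccentricity fades, and report the moment of complete filling-in (the
filling-in time, FT).  Binocular gaze is simulated as a conjugate 2-D
random-walk drift plus ballistic microsaccades obeying the main-sequence
amplitude/peak-velocity relation, with blinks and per-eye white measurement
noise.  Trial outcomes (log FT) are drawn from a linear mixed-effects
structure — fixed effects on standardized stimulus and oculomotor covariates,
per-participant random intercept and slopes, Gaussian residual — so every
downstream stage (detection, metrics, rate dynamics, model fitting) can be
validated against known truth.

Two deliberate calibration choices:

- Event counts are drawn *before* the outcome, over a nominal trial duration,
  from a gamma-Poisson (negative-binomial) mixture.  The overdispersion
  reproduces the realistic ~10% fraction of trials with no detectable
  microsaccades at a ~0.9 Hz mean rate, which a homogeneous Poisson process
  cannot produce; it also breaks the circular dependency between
  microsaccade presence (a covariate) and trial duration (the outcome).
- Outcome coefficients live on a standardized log-FT scale; an explicit
  ``ft_log_offset`` shifts simulated FTs onto a realistic seconds scale
  without touching the coefficients a fit must recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import calibration
from .gaze import GazeTrace

ARCMIN_PER_DEG = 60.0

#: terms of the primary filling-in-time model formula (non-intercept)
PRIMARY_TERMS = (
    "contrast",
    "eccentricity",
    "trial_num",
    "ms_presence",
    "num_blinks",
    "contrast:trial_num",
    "ms_presence:contrast",
    "ms_presence:eccentricity",
    "num_blinks:contrast",
    "num_blinks:eccentricity",
)

#: covariates standardized before entering the linear predictor
CONTINUOUS_COVARIATES = ("contrast", "eccentricity", "trial_num", "num_blinks")


@dataclass
class SimConfig:
    """Design and signal parameters of a synthetic experiment.

    Defaults reproduce the study conditions: 21 participants x 9 blocks
    (3 colour contrasts x 3 eccentricities) x 40 main trials, 1000 Hz
    binocular gaze, ~0.89 Hz mean microsaccade rate.
    """

    n_participants: int = 21
    blocks: tuple = calibration.DEFAULT_BLOCKS  # (contrast_level, eccentricity_deg)
    trials_per_block: int = 40
    sampling_rate: float = 1000.0  # Hz
    ms_rate: float = calibration.MEAN_MS_RATE_HZ  # Hz, mean across trials
    ms_dispersion: float = 1.3  # gamma shape of the per-trial rate mixture
    drift_diffusion: float = 4e-4  # deg^2/s, 2-D random walk
    noise_sd: float = 0.1  # arcmin per sample per eye
    main_sequence_slope: float = 60.0  # (deg/s) peak velocity per deg amplitude
    amp_median_arcmin: float = 20.0  # median injected amplitude
    amp_log_sd: float = 0.7  # lognormal sd of injected amplitudes
    amp_bounds_arcmin: tuple = (3.0, 90.0)  # truncation of injected amplitudes
    blink_rate: float = 0.1  # Hz
    blink_duration_ms: tuple = (100.0, 300.0)
    max_trial_s: float = 20.0
    min_trial_s: float = 2.0
    pre_press_quiet_ms: float = 600.0  # window of microsaccade suppression
    dip_depth: float = 0.8  # probability an event is relocated out of the window
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ms_rate", "drift_diffusion", "noise_sd", "blink_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sampling_rate <= 0 or self.main_sequence_slope <= 0:
            raise ValueError("sampling_rate and main_sequence_slope must be positive")
        for c, e in self.blocks:
            if c not in calibration.CONTRAST_LEVELS or e not in calibration.ECCENTRICITY_LEVELS_DEG:
                raise ValueError(f"block ({c}, {e}) outside the printed design levels")

    @property
    def saccade_duration_s(self) -> float:
        """Raised-cosine duration consistent with the main sequence.

        A raised-cosine velocity profile with peak ``slope * A`` displaces the
        eye by ``peak * T / 2``; requiring displacement = amplitude fixes
        ``T = 2 / slope`` independent of amplitude.
        """
        return 2.0 / self.main_sequence_slope


@dataclass
class InjectedEvent:
    """Ground-truth microsaccade parameters."""

    onset_s: float
    amplitude_deg: float
    direction_deg: float


@dataclass
class GroundTruth:
    """Generative coefficients and injected events of a synthetic experiment.

    ``fixed_effects`` are on the standardized log-FT scale and must name a
    subset of the primary model terms (plus the intercept);
    ``random_effect_sds`` are per-participant SDs for the intercept and any
    random slopes; ``ft_log_offset`` maps the coefficient scale onto log
    seconds so simulated FTs land near the observed task mean.
    """

    fixed_effects: dict = field(
        default_factory=lambda: dict(calibration.FT_PRIMARY_COEFS))
    random_effect_sds: dict = field(
        default_factory=lambda: {
            "intercept": 0.2,
            "contrast": 0.05,
            "eccentricity": 0.05,
            "trial_num": 0.05,
            "ms_presence": 0.05,
            "num_blinks": 0.05,
        })
    residual_sd: float = 0.3
    ft_log_offset: float | None = None  # resolved at generation: maps the
    # model-implied mean log FT (incl. the non-centred binary ms_presence
    # covariate and the lognormal mean correction) onto the observed task mean
    injected_events: dict = field(default_factory=dict)  # trial_id -> list[InjectedEvent]
    injected_blinks: dict = field(default_factory=dict)  # trial_id -> list[(on_s, off_s)]

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        allowed = set(PRIMARY_TERMS) | {"intercept"}
        unknown = set(self.fixed_effects) - allowed
        if unknown:
            raise ValueError(f"fixed effects not in the primary model formula: {sorted(unknown)}")
        bad = {k: v for k, v in self.random_effect_sds.items() if v < 0}
        if bad:
            raise ValueError(f"negative random-effect SDs: {bad}")


# --------------------------------------------------------------------------
# trace synthesis
# --------------------------------------------------------------------------

def _raised_cosine_displacement(t: np.ndarray, event: InjectedEvent, duration_s: float) -> np.ndarray:
    """Cumulative 2-D displacement of one ballistic event at times t (s)."""
    u = np.clip((t - event.onset_s) / duration_s, 0.0, 1.0)
    s = event.amplitude_deg * (u - np.sin(2 * np.pi * u) / (2 * np.pi))
    phi = np.radians(event.direction_deg)
    return np.outer(s, [np.cos(phi), np.sin(phi)])


def generate_trace(
    duration_s: float,
    ms_events: list[InjectedEvent],
    blink_intervals: list[tuple[float, float]],
    cfg: SimConfig,
    seed: int | np.random.Generator = 0,
    participant: str | None = None,
    trial: int | None = None,
) -> GazeTrace:
    """Synthesize one binocular gaze trace.

    Drift is a conjugate 2-D random walk with diffusion ``cfg.drift_diffusion``;
    each microsaccade is a conjugate ballistic displacement with a raised-cosine
    velocity profile whose peak equals ``main_sequence_slope * amplitude``;
    blinks invalidate samples and erase position; white positional noise of SD
    ``cfg.noise_sd`` arcmin is added independently per eye.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    fs = cfg.sampling_rate
    n = int(round(duration_s * fs)) + 1
    if n < 31:
        raise ValueError("trace shorter than one velocity window")
    T = cfg.saccade_duration_s
    events = sorted(ms_events, key=lambda ev: ev.onset_s)
    for ev in events:
        if ev.onset_s < 0 or ev.onset_s + T > duration_s + 1e-9:
            raise ValueError("injected event outside the trace duration")
    for a, b in zip(events, events[1:]):
        if b.onset_s < a.onset_s + T:
            raise ValueError("injected events overlap")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1.0 / fs
    t = np.arange(n) * dt

    step_sd = math.sqrt(cfg.drift_diffusion * dt)
    drift = np.vstack([np.zeros((1, 2)), np.cumsum(rng.normal(0.0, step_sd, (n - 1, 2)), axis=0)])

    pos = drift.copy()
    for ev in events:
        pos += _raised_cosine_displacement(t, ev, T)

    noise_sd_deg = cfg.noise_sd / ARCMIN_PER_DEG
    left = pos + rng.normal(0.0, noise_sd_deg, (n, 2))
    right = pos + rng.normal(0.0, noise_sd_deg, (n, 2))

    valid = np.ones(n, dtype=bool)
    for on_s, off_s in blink_intervals:
        i0 = max(0, int(math.floor(on_s * fs)))
        i1 = min(n - 1, int(math.ceil(off_s * fs)))
        valid[i0:i1 + 1] = False
    left[~valid] = np.nan
    right[~valid] = np.nan

    return GazeTrace(
        time_ms=t * 1000.0,
        left=left,
        right=right,
        valid_left=valid.copy(),
        valid_right=valid.copy(),
        sampling_rate=fs,
        participant=participant,
        trial=trial,
    )


# --------------------------------------------------------------------------
# design and outcome simulation
# --------------------------------------------------------------------------

def design_table(cfg: SimConfig, seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Raw trial design: participant, block (randomized order), contrast,
    eccentricity, within-block trial number."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(cfg.seed if seed is None else seed))
    rows = []
    for p in range(cfg.n_participants):
        pid = f"p{p + 1:02d}"
        order = rng.permutation(len(cfg.blocks))
        for b_idx, b in enumerate(order):
            contrast, ecc = cfg.blocks[b]
            for tr in range(1, cfg.trials_per_block + 1):
                rows.append((pid, b_idx, tr, "main", contrast, ecc))
    return pd.DataFrame(rows, columns=["participant", "block", "trial_num",
                                       "trial_type", "contrast", "eccentricity"])


def _standardize(col: np.ndarray) -> np.ndarray:
    """Population z-score; a constant covariate maps to zeros (its effect is
    then absorbed by the intercept, e.g. num_blinks when blinks are off)."""
    sd = col.std()  # population SD (ddof=0)
    if sd == 0:
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":")
        return df[a].to_numpy(float) * df[b].to_numpy(float)
    return df[term].to_numpy(float)


def simulate_outcome(
    design: pd.DataFrame,
    coefs: dict,
    re_sds: dict,
    residual_sd: float,
    seed: int | np.random.Generator = 0,
    group_col: str = "participant",
    offset: float = 0.0,
) -> np.ndarray:
    """Draw a mixed-model outcome over an existing design table.

    ``design`` must already hold the model-scale (e.g. standardized) covariate
    columns; interaction terms named "a:b" are formed as products.  Random
    effects are independent normal per group and term; ``re_sds`` must contain
    at least an "intercept" entry.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = design[group_col].to_numpy()
    uniq, gidx = np.unique(groups, return_inverse=True)
    missing = [t for t in coefs if t != "intercept"
               and (t.split(":")[0] not in design.columns
                    or t.split(":")[-1] not in design.columns)]
    if missing:
        raise ValueError(f"design lacks columns for model terms: {missing}")

    y = np.full(len(design), offset + coefs.get("intercept", 0.0))
    y = y + rng.normal(0.0, re_sds.get("intercept", 0.0), len(uniq))[gidx]
    for term, beta in coefs.items():
        if term == "intercept":
            continue
        x = _term_column(design, term)
        slope = beta + (rng.normal(0.0, re_sds[term], len(uniq))[gidx]
                        if term in re_sds and re_sds[term] > 0 else 0.0)
        y = y + slope * x
    return y + rng.normal(0.0, residual_sd, len(design))


def _presence_prob(cfg: SimConfig, t_ref: float) -> float:
    """Marginal P(any microsaccade) under the gamma-Poisson count mixture.

    Uses the gamma Laplace transform: E[exp(-g mu)] = (1 + mu/k)^(-k) for a
    unit-mean gamma multiplier with shape k.
    """
    mu = cfg.ms_rate * t_ref
    if mu <= 0:
        return 0.0
    k = cfg.ms_dispersion
    return 1.0 - (1.0 + mu / k) ** (-k) if k > 0 else 1.0 - math.exp(-mu)


def _resolve_scale(cfg: SimConfig, truth: GroundTruth) -> tuple[float, float, float]:
    """Resolve (ft_log_offset, nominal duration, presence probability).

    When ``truth.ft_log_offset`` is None, the offset is chosen so the
    model-implied arithmetic mean FT equals the observed task mean: the mean
    log FT is offset + intercept + beta_presence * P(presence) (standardized
    covariates contribute zero on average; ms_presence is binary and
    non-centred), plus the lognormal mean correction sigma^2/2.
    """
    beta0 = truth.fixed_effects.get("intercept", 0.0)
    beta_p = truth.fixed_effects.get("ms_presence", 0.0)
    sigma2 = truth.residual_sd**2 + sum(s**2 for s in truth.random_effect_sds.values())
    if truth.ft_log_offset is None:
        t_ref = min(calibration.MEAN_FT_S, cfg.max_trial_s)
        p_bar = _presence_prob(cfg, t_ref)
        offset = math.log(t_ref) - sigma2 / 2.0 - beta0 - beta_p * p_bar
    else:
        offset = truth.ft_log_offset
        t_ref = min(math.exp(offset + beta0 + sigma2 / 2.0), cfg.max_trial_s)
        p_bar = _presence_prob(cfg, t_ref)
        t_ref = min(math.exp(offset + beta0 + beta_p * p_bar + sigma2 / 2.0), cfg.max_trial_s)
        p_bar = _presence_prob(cfg, t_ref)
    return offset, t_ref, p_bar


def _place_events(rng: np.random.Generator, n_events: int, ft_s: float, cfg: SimConfig) -> list[float]:
    """Non-overlapping event onsets in [0, ft], with pre-report suppression."""
    T = cfg.saccade_duration_s
    hi = ft_s - T
    if hi <= 0 or n_events == 0:
        return []
    n_events = min(n_events, max(1, int(hi / (T + 0.002))))
    for _ in range(200):
        onsets = np.sort(rng.uniform(0.0, hi, n_events))
        if n_events == 1 or np.all(np.diff(onsets) >= T + 0.002):
            break
    else:
        onsets = np.arange(n_events) * (T + 0.002)
    quiet = cfg.pre_press_quiet_ms / 1000.0
    cap = ft_s - quiet - T
    if quiet > 0 and cap > 0:
        moved = list(onsets)
        for i, on in enumerate(moved):
            if on + T > ft_s - quiet and rng.random() < cfg.dip_depth:
                for _ in range(50):
                    cand = rng.uniform(0.0, cap)
                    others = [o for j, o in enumerate(moved) if j != i]
                    if all(abs(cand - o) >= T + 0.002 for o in others):
                        moved[i] = cand
                        break
        onsets = np.sort(moved)
    return [float(v) for v in onsets]


def _draw_amplitude(rng: np.random.Generator, cfg: SimConfig) -> float:
    lo, hi = cfg.amp_bounds_arcmin
    for _ in range(1000):
        a = math.exp(rng.normal(math.log(cfg.amp_median_arcmin), cfg.amp_log_sd))
        if lo <= a <= hi:
            return a / ARCMIN_PER_DEG
    return cfg.amp_median_arcmin / ARCMIN_PER_DEG


def generate_experiment(
    cfg: SimConfig,
    truth: GroundTruth | None = None,
    seed: int | None = None,
    with_traces: bool = True,
) -> tuple[pd.DataFrame, dict, GroundTruth]:
    """Generate a complete synthetic experiment.

    Returns ``(trials, traces, truth)``: a trial table (one row per trial with
    design, oculomotor covariates and the filling-in time), a dict of
    :class:`GazeTrace` keyed by ``trial_id`` (empty when ``with_traces`` is
    False), and the ground truth actually used, with injected events and
    blinks recorded per trial.

    Per trial: microsaccade and blink counts are drawn over the nominal trial
    duration (gamma-Poisson for microsaccades, Poisson for blinks); covariates
    are standardized; log FT is drawn from the mixed-model structure, redrawn
    above the ``min_trial_s`` floor (so trials pass the short-trial filter)
    and capped at the ``max_trial_s`` timeout (latent value preserved in
    ``log_ft_true``); event onsets are then placed within the realized trial,
    suppressed in the final ``pre_press_quiet_ms`` to emulate the pre-report
    rate dip.
    """
    truth = truth or GroundTruth()
    missing = [t for t in truth.random_effect_sds if t != "intercept" and t not in PRIMARY_TERMS]
    if missing:
        raise ValueError(f"random-effect terms outside the primary formula: {missing}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = replace(truth, injected_events={}, injected_blinks={})

    trials = design_table(cfg, rng)
    n = len(trials)
    beta0 = truth.fixed_effects.get("intercept", 0.0)
    offset, t_ref, _ = _resolve_scale(cfg, truth)
    truth = replace(truth, ft_log_offset=offset)

    disp = rng.gamma(cfg.ms_dispersion, 1.0 / cfg.ms_dispersion, n) if cfg.ms_dispersion > 0 else np.ones(n)
    ms_count = rng.poisson(disp * cfg.ms_rate * t_ref)
    num_blinks = rng.poisson(cfg.blink_rate * t_ref, n)
    trials["ms_count"] = ms_count
    trials["ms_presence"] = (ms_count > 0).astype(int)
    trials["num_blinks"] = num_blinks

    std = trials.copy()
    for c in CONTINUOUS_COVARIATES:
        std[c] = _standardize(std[c].to_numpy(float))

    groups = trials["participant"].to_numpy()
    uniq, gidx = np.unique(groups, return_inverse=True)
    b = {t: rng.normal(0.0, s, len(uniq)) for t, s in truth.random_effect_sds.items()}
    eta = np.full(n, beta0) + b.get("intercept", np.zeros(len(uniq)))[gidx]
    for term, coef in truth.fixed_effects.items():
        if term == "intercept":
            continue
        x = _term_column(std, term)
        slope = coef + (b[term][gidx] if term in b else 0.0)
        eta = eta + slope * x

    # Lower bound: redraw the residual so trials pass the short-trial filter
    # (rare at the default calibration).  Upper bound: the task's timeout caps
    # the realized trial duration, but the latent outcome is preserved in
    # ``log_ft_true`` — redraw-truncation at the timeout would attenuate the
    # injected coefficients and defeat parameter recovery.
    lo, hi = math.log(cfg.min_trial_s), math.log(cfg.max_trial_s)
    log_ft = truth.ft_log_offset + eta + rng.normal(0.0, truth.residual_sd, n)
    for _ in range(1000):
        out = log_ft < lo
        if not out.any():
            break
        log_ft[out] = truth.ft_log_offset + eta[out] + rng.normal(0.0, truth.residual_sd, int(out.sum()))
    np.clip(log_ft, lo, None, out=log_ft)
    ft_s = np.exp(np.minimum(log_ft, hi))
    trials["ft_ms"] = ft_s * 1000.0
    trials["log_ft_true"] = log_ft

    trial_ids = (trials["participant"] + "_b" + trials["block"].astype(str)
                 + "_t" + trials["trial_num"].astype(str))
    trials.insert(0, "trial_id", trial_ids)

    traces: dict[str, GazeTrace] = {}
    blink_lo, blink_hi = (d / 1000.0 for d in cfg.blink_duration_ms)
    for i in range(n):
        tid = trials["trial_id"].iat[i]
        onsets = _place_events(rng, int(ms_count[i]), float(ft_s[i]), cfg)
        # microsaccades are error-correcting: once gaze has strayed from the
        # fixation point, directions bias back toward it, keeping fixation
        # bounded as in real data (uniform directions would random-walk away)
        events = []
        cum = np.zeros(2)
        for o in onsets:
            amp = _draw_amplitude(rng, cfg)
            if np.hypot(*cum) > 0.2:
                direction = math.degrees(math.atan2(-cum[1], -cum[0])) + rng.uniform(-60.0, 60.0)
            else:
                direction = rng.uniform(0.0, 360.0)
            direction = float(direction % 360.0)
            events.append(InjectedEvent(onset_s=o, amplitude_deg=amp, direction_deg=direction))
            cum += amp * np.array([math.cos(math.radians(direction)),
                                   math.sin(math.radians(direction))])
        blinks = []
        for _ in range(int(num_blinks[i])):
            d = rng.uniform(blink_lo, blink_hi)
            if ft_s[i] > d:
                on = rng.uniform(0.0, ft_s[i] - d)
                blinks.append((float(on), float(on + d)))
        truth.injected_events[tid] = events
        truth.injected_blinks[tid] = sorted(blinks)
        trials.loc[trials.index[i], "ms_count"] = len(events)
        trials.loc[trials.index[i], "ms_presence"] = int(len(events) > 0)
        if with_traces:
            traces[tid] = generate_trace(
                float(ft_s[i]), events, blinks, cfg, rng,
                participant=trials["participant"].iat[i],
                trial=int(trials["trial_num"].iat[i]),
            )
    return trials, traces, truth
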