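"""Parameter-recovery simulation studies.

Each function generates synthetic experiments with the published fixed-effect
estimates injected as ground truth, re-fits the corresponding mixed model,
and returns the recovered coefficients per replicate.  These studies are the
package's central validation surface: they demonstrate that the full chain —
generator, standardization, REML fitting — returns the coefficients it was
given, at realistic sample sizes (21 participants x 360 trials for the
full-design models; 630 trials for the balanced-subset model).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibration
from .models import (
    fit_lmm,
    immobilization_spec,
    ms_rate_spec,
    primary_ft_spec,
    standardize_predictors,
    subset_spec,
)
from .synth import GroundTruth, SimConfig, design_table, generate_experiment, simulate_outcome

#: default per-participant random-effect SDs of the outcome simulations
DEFAULT_RE_SDS = {"intercept": 0.2}
DEFAULT_RESIDUAL_SD = 0.3


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def recover_primary(n_reps: int = 10, seed: int = 0,
                    truth: GroundTruth | None = None) -> pd.DataFrame:
    """Re-fit the primary log-FT model on experiments generated from it.

    Generates a full-design experiment per replicate (traces off — the
    outcome model is what is under test), fits the primary spec on the latent
    log FT, and returns one row of recovered fixed effects per replicate.
    """
    rows = []
    for s in _spawn_seeds(seed, n_reps):
        trials, _, _ = generate_experiment(
            SimConfig(seed=s), truth, with_traces=False)
        df = trials.copy()
        df["log_ft"] = df["log_ft_true"]
        fit = fit_lmm(primary_ft_spec(), df)
        rows.append(fit.estimates)
    return pd.DataFrame(rows)


def _subset_design(rng: np.random.Generator, n_participants: int = 21,
                   trials_each: int = 30) -> pd.DataFrame:
    blocks = calibration.DEFAULT_BLOCKS
    rows = []
    for p in range(n_participants):
        pid = f"p{p + 1:02d}"
        for _ in range(trials_each):
            c, e = blocks[rng.integers(len(blocks))]
            rows.append((pid, c, e, int(rng.integers(1, 41)),
                         max(0.05, rng.normal(0.75, 0.15))))
    return pd.DataFrame(rows, columns=["participant", "contrast", "eccentricity",
                                       "trial_num", "ocular_drift"])


def recover_subset(n_reps: int = 10, seed: int = 0,
                   coefs: dict | None = None) -> pd.DataFrame:
    """Recovery of the balanced microsaccade-trials subset model.

    630 trials across 21 participants, random intercept only, predictors
    contrast, eccentricity, trial number and ocular drift.
    """
    coefs = coefs or calibration.FT_SUBSET_MS_COEFS
    rows = []
    for s in _spawn_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        design, _ = standardize_predictors(_subset_design(rng))
        design["log_ft"] = simulate_outcome(
            design, coefs, DEFAULT_RE_SDS, DEFAULT_RESIDUAL_SD, rng)
        rows.append(fit_lmm(subset_spec(), design).estimates)
    return pd.DataFrame(rows)


def recover_ms_rate(n_reps: int = 10, seed: int = 0,
                    coefs: dict | None = None) -> pd.DataFrame:
    """Recovery of the trial-wise log microsaccade-rate model (full design)."""
    coefs = coefs or calibration.MS_RATE_COEFS
    re_sds = dict(DEFAULT_RE_SDS, contrast=0.05, eccentricity=0.05, trial_num=0.05)
    rows = []
    for s in _spawn_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        design, _ = standardize_predictors(design_table(SimConfig(seed=s), rng))
        design["log_ms_rate"] = simulate_outcome(
            design, coefs, re_sds, DEFAULT_RESIDUAL_SD, rng)
        rows.append(fit_lmm(ms_rate_spec(), design).estimates)
    return pd.DataFrame(rows)


def recover_immobilization(n_reps: int = 10, seed: int = 0,
                           coefs: dict | None = None) -> pd.DataFrame:
    """Recovery of the log immobilization-time model (full design plus the
    last-microsaccade amplitude as a covariate)."""
    coefs = coefs or calibration.IMMOBILIZATION_COEFS
    re_sds = dict(DEFAULT_RE_SDS, contrast=0.05, eccentricity=0.05,
                  trial_num=0.05, ms_amplitude=0.05)
    rows = []
    for s in _spawn_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        design = design_table(SimConfig(seed=s), rng)
        design["ms_amplitude"] = np.exp(rng.normal(np.log(0.33), 0.7, len(design)))
        design, _ = standardize_predictors(design)
        design["log_immobilization"] = simulate_outcome(
            design, coefs, re_sds, DEFAULT_RESIDUAL_SD, rng)
        rows.append(fit_lmm(immobilization_spec(), design).estimates)
    return pd.DataFrame(rows)
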