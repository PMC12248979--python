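"""Linear mixed models of trial outcomes with case-bootstrap inference.

Fits REML linear mixed models of log-transformed trial outcomes (filling-in
time, microsaccade rate, immobilization time) with a per-participant random
intercept and, where specified, independent random slopes fitted as variance
components.  Inference on fixed effects uses a participant-level case
bootstrap: whole participants are resampled with replacement, the model is
refitted, and percentile confidence intervals are taken at a
Bonferroni-corrected level (alpha divided by the number of non-intercept
fixed effects).  Also provides BIC-guided term retention, balanced subset
models, and the cortical-magnification eccentricity transform.

The random-effect covariance is fitted as independent (diagonal) variance
components rather than a full covariance: with ~20 participants a
six-dimensional correlated structure is fragile, and fixed-effect estimates
— the quantities of interest here — are robust to this choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: predictors standardized when present (binary indicators are never scaled)
CONTINUOUS_PREDICTORS = (
    "contrast",
    "eccentricity",
    "trial_num",
    "num_blinks",
    "ocular_drift",
    "ms_amplitude",
)

RESPONSES = ("log_ft", "log_ms_rate", "log_immobilization")


@dataclass
class ModelSpec:
    """A mixed-model formula: response, fixed terms, random slopes.

    Interactions are written "a:b"; each interaction's parents must appear as
    main effects, and random slopes must be a subset of the fixed main
    effects.  A per-participant random intercept is always included.
    """

    response: str
    fixed_terms: tuple
    random_terms: tuple = ()
    standardize: bool = True
    group_col: str = "participant"

    def __post_init__(self) -> None:
        self.fixed_terms = tuple(self.fixed_terms)
        self.random_terms = tuple(self.random_terms)
        mains = {t for t in self.fixed_terms if ":" not in t}
        for t in self.fixed_terms:
            if ":" in t:
                for p in t.split(":"):
                    if p not in mains:
                        raise ValueError(f"interaction {t} lacks main effect {p}")
        extra = set(self.random_terms) - mains - {"intercept"}
        if extra:
            raise ValueError(f"random slopes without fixed main effects: {sorted(extra)}")


def primary_ft_spec() -> ModelSpec:
    """Primary filling-in-time model: stimulus and oculomotor main effects,
    their critical interactions, and random slopes for all main effects."""
    return ModelSpec(
        response="log_ft",
        fixed_terms=(
            "contrast", "eccentricity", "trial_num", "ms_presence", "num_blinks",
            "contrast:trial_num", "ms_presence:contrast", "ms_presence:eccentricity",
            "num_blinks:contrast", "num_blinks:eccentricity",
        ),
        random_terms=("contrast", "eccentricity", "trial_num", "ms_presence", "num_blinks"),
    )


def ms_rate_spec() -> ModelSpec:
    """Trial-wise log microsaccade rate vs stimulus properties."""
    return ModelSpec(
        response="log_ms_rate",
        fixed_terms=("contrast", "eccentricity", "trial_num"),
        random_terms=("contrast", "eccentricity", "trial_num"),
    )


def immobilization_spec() -> ModelSpec:
    """Log immobilization time vs stimulus properties and last-event amplitude."""
    return ModelSpec(
        response="log_immobilization",
        fixed_terms=("contrast", "eccentricity", "ms_amplitude", "trial_num"),
        random_terms=("contrast", "eccentricity", "ms_amplitude", "trial_num"),
    )


def subset_spec() -> ModelSpec:
    """Random-intercept-only model used on the balanced trial subsets."""
    return ModelSpec(
        response="log_ft",
        fixed_terms=("contrast", "eccentricity", "trial_num", "ocular_drift"),
        random_terms=(),
    )


@dataclass
class FitResult:
    """Fixed-effect estimates and fit diagnostics of one mixed model."""

    estimates: dict
    random_sd: dict
    resid_sd: float
    loglik: float
    bic: float
    n_obs: int
    converged: bool
    reml: bool
    scalers: dict = field(default_factory=dict)  # predictor -> (mean, sd)
    spec: ModelSpec | None = None


@dataclass
class BootstrapResult:
    """Participant-level case-bootstrap percentile intervals."""

    terms: tuple
    samples: np.ndarray  # (n_kept, n_terms)
    n_boot: int
    n_converged: int
    alpha: float
    alpha_corrected: float
    ci: dict
    significant: dict

    def ci_at(self, alpha: float) -> dict:
        """Percentile CIs on the same resamples at another level.

        Tail quantiles round outward to order statistics (conservative at
        modest resample counts, where interpolated tails run narrow).
        """
        lo = 100 * alpha / 2
        out = {}
        for j, t in enumerate(self.terms):
            out[t] = (float(np.percentile(self.samples[:, j], lo, method="lower")),
                      float(np.percentile(self.samples[:, j], 100 - lo, method="higher")))
        return out


def standardize_predictors(
    df: pd.DataFrame,
    predictors: tuple | list | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Zero-center and unit-scale continuous predictors (population SD).

    Binary indicators are left untouched.  Returns the transformed table and
    the (mean, sd) pairs used, for inversion.  A zero-variance predictor is
    rejected by name.
    """
    preds = [p for p in (predictors or CONTINUOUS_PREDICTORS) if p in df.columns]
    out = df.copy()
    scalers: dict = {}
    for p in preds:
        x = out[p].to_numpy(float)
        vals = np.unique(x[np.isfinite(x)])
        if set(vals.tolist()) <= {0.0, 1.0}:
            continue  # binary stays binary
        sd = float(np.std(x))
        if sd == 0:
            raise ValueError(f"predictor '{p}' has zero variance")
        m = float(np.mean(x))
        out[p] = (x - m) / sd
        scalers[p] = (m, sd)
    return out, scalers


def back_transform(estimates: dict, scalers: dict) -> dict:
    """Rewrite standardized-scale coefficients on the raw predictor scale.

    Exact algebraic inversion for main effects and two-way products, so
    fixed-effect predictions from the raw-scale coefficients on raw data equal
    those from the standardized coefficients on standardized data.
    """
    out: dict = {"intercept": estimates.get("intercept", 0.0)}

    def ms(term: str) -> tuple[float, float]:
        return scalers.get(term, (0.0, 1.0))

    for term, beta in estimates.items():
        if term == "intercept":
            continue
        parts = term.split(":")
        if len(parts) == 1:
            m, s = ms(term)
            out[term] = out.get(term, 0.0) + beta / s
            out["intercept"] -= beta * m / s
        elif len(parts) == 2:
            (ma, sa), (mb, sb) = ms(parts[0]), ms(parts[1])
            out[term] = out.get(term, 0.0) + beta / (sa * sb)
            out[parts[0]] = out.get(parts[0], 0.0) - beta * mb / (sa * sb)
            out[parts[1]] = out.get(parts[1], 0.0) - beta * ma / (sa * sb)
            out["intercept"] += beta * ma * mb / (sa * sb)
        else:
            raise ValueError(f"cannot invert term of order > 2: {term}")
    return out


def predict_fixed(coefs: dict, df: pd.DataFrame) -> np.ndarray:
    """Fixed-effect linear predictor of ``coefs`` over ``df`` columns."""
    y = np.full(len(df), coefs.get("intercept", 0.0))
    for term, beta in coefs.items():
        if term == "intercept":
            continue
        x = np.ones(len(df))
        for p in term.split(":"):
            x = x * df[p].to_numpy(float)
        y = y + beta * x
    return y


def _prepare(spec: ModelSpec, df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    needed = {p for t in spec.fixed_terms for p in t.split(":")}
    missing = sorted(needed - set(df.columns)) + ([spec.response] if spec.response not in df.columns else [])
    if missing:
        raise ValueError(f"data lacks required columns: {missing}")
    data = df.dropna(subset=[spec.response]).copy()
    scalers: dict = {}
    if spec.standardize:
        data, scalers = standardize_predictors(data, sorted(needed & set(CONTINUOUS_PREDICTORS)))
    return data, scalers


def fit_lmm(spec: ModelSpec, df: pd.DataFrame, reml: bool = True) -> FitResult:
    """REML (or ML) fit of ``spec`` with random intercept + diagonal slopes.

    Non-convergence is flagged on the result, never silently accepted.  BIC
    is ``-2 logL + p log n`` with p counting fixed effects, variance
    parameters and the residual variance; for model comparison across fixed
    effects, use ML fits (``reml=False``).
    """
    if df[spec.group_col].nunique() < 2:
        raise ValueError("at least 2 participants required")
    data, scalers = _prepare(spec, df)
    if not np.isfinite(data[spec.response].to_numpy(float)).all():
        raise ValueError("non-finite response values")
    formula = f"{spec.response} ~ " + " + ".join(spec.fixed_terms) if spec.fixed_terms else f"{spec.response} ~ 1"
    slopes = [t for t in spec.random_terms if t != "intercept"]
    vc = {t: f"0 + {t}" for t in slopes}
    endog_var = float(np.var(data[spec.response].to_numpy(float)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            formula, groups=spec.group_col, re_formula="1",
            vc_formula=vc or None, data=data,
        )
        # Gradient-based optimizers occasionally stall or fail outright on
        # near-degenerate variance profiles; Powell is slower but far more
        # robust, so it backs up the default whenever the first fit looks off
        # (including a residual variance exceeding the data variance, the
        # signature of a silently failed fit).
        try:
            res = model.fit(reml=reml)
        except (np.linalg.LinAlgError, ValueError):
            res = None
        suspicious = (res is None or not res.converged or not np.isfinite(res.llf)
                      or res.scale > 1.5 * endog_var + 1e-10)
        if suspicious:
            try:
                res2 = model.fit(reml=reml, method="powell")
            except (np.linalg.LinAlgError, ValueError):
                res2 = None
            if res2 is not None and np.isfinite(res2.llf) and (
                    res is None or not np.isfinite(res.llf) or res2.llf >= res.llf):
                res = res2
        if res is None:
            raise np.linalg.LinAlgError("mixed-model fit failed on all optimizers")
    estimates = {("intercept" if k == "Intercept" else k): float(v)
                 for k, v in res.fe_params.items()}
    random_sd = {"intercept": float(np.sqrt(res.cov_re.iloc[0, 0]))}
    for t in slopes:
        random_sd[t] = float(np.sqrt(res.vcomp[list(model.exog_vc.names).index(t)]))
    n = int(res.nobs)
    p = len(res.params) + 1  # + residual variance
    llf = float(res.llf)
    return FitResult(
        estimates=estimates,
        random_sd=random_sd,
        resid_sd=float(np.sqrt(res.scale)),
        loglik=llf,
        bic=-2.0 * llf + p * np.log(n),
        n_obs=n,
        converged=bool(res.converged),
        reml=reml,
        scalers=scalers,
        spec=spec,
    )


def case_bootstrap(
    spec: ModelSpec,
    df: pd.DataFrame,
    n_boot: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    max_nonconverged_frac: float = 0.2,
) -> BootstrapResult:
    """Participant-level case bootstrap of the fixed effects.

    Each iteration resamples whole participants with replacement (relabelled
    uniquely so duplicated participants stay distinct grouping units), refits
    the model, and records the fixed effects.  Percentile CIs are formed at
    the Bonferroni-corrected level ``alpha / k`` with k the number of
    non-intercept fixed effects; a term is flagged significant when its
    corrected CI excludes 0.  Aborts if more than ``max_nonconverged_frac``
    of iterations fail to converge.
    """
    base = fit_lmm(spec, df)
    if not base.converged:
        raise RuntimeError("full-data fit did not converge")
    terms = tuple(base.estimates)
    k = max(1, sum(1 for t in terms if t != "intercept"))
    alpha_c = alpha / k
    rng = np.random.default_rng(seed)
    participants = np.asarray(sorted(df[spec.group_col].unique()))
    samples = []
    n_fail = 0
    for _ in range(n_boot):
        chosen = rng.choice(participants, size=len(participants), replace=True)
        parts = []
        for j, pid in enumerate(chosen):
            sub = df[df[spec.group_col] == pid].copy()
            sub[spec.group_col] = f"bs{j:03d}_{pid}"
            parts.append(sub)
        bdf = pd.concat(parts, ignore_index=True)
        try:
            fit = fit_lmm(spec, bdf)
        except (ValueError, np.linalg.LinAlgError):
            n_fail += 1
            continue
        if not fit.converged:
            n_fail += 1
            continue
        samples.append([fit.estimates[t] for t in terms])
    if n_fail > max_nonconverged_frac * n_boot:
        raise RuntimeError(f"{n_fail}/{n_boot} bootstrap iterations failed to converge")
    arr = np.asarray(samples)
    result = BootstrapResult(
        terms=terms, samples=arr, n_boot=n_boot, n_converged=len(samples),
        alpha=alpha, alpha_corrected=alpha_c, ci={}, significant={},
    )
    result.ci = result.ci_at(alpha_c)
    result.significant = {t: not (lo <= 0.0 <= hi) for t, (lo, hi) in result.ci.items()}
    return result


def select_terms_by_bic(
    spec: ModelSpec,
    df: pd.DataFrame,
    candidates: tuple | list | None = None,
) -> ModelSpec:
    """Drop each candidate term whose removal lowers the (ML) BIC.

    Candidates default to all non-intercept fixed terms; a main effect that
    parents a retained interaction is never removed.  Terms whose removal
    does not improve fit are retained.
    """
    base = fit_lmm(spec, df, reml=False)
    if not base.converged:
        raise RuntimeError("base fit did not converge")
    cands = list(candidates) if candidates is not None else list(spec.fixed_terms)
    removed = []
    for term in cands:
        if term not in spec.fixed_terms:
            raise ValueError(f"candidate {term} not in the model")
        parents_needed = {p for t in spec.fixed_terms if ":" in t and t != term for p in t.split(":")}
        if ":" not in term and term in parents_needed:
            continue
        reduced = replace(
            spec,
            fixed_terms=tuple(t for t in spec.fixed_terms if t != term),
            random_terms=tuple(t for t in spec.random_terms if t != term),
        )
        try:
            fit = fit_lmm(reduced, df, reml=False)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if fit.converged and fit.bic < base.bic:
            removed.append(term)
    return replace(
        spec,
        fixed_terms=tuple(t for t in spec.fixed_terms if t not in removed),
        random_terms=tuple(t for t in spec.random_terms if t not in removed),
    )


def subset_models(
    df: pd.DataFrame,
    seed: int = 0,
    spec: ModelSpec | None = None,
) -> dict:
    """Balanced comparison of microsaccade-present vs microsaccade-free trials.

    Splits blink-free trials by microsaccade presence, downsamples the larger
    subset per participant to match the smaller (the smaller subset is never
    altered), and fits a random-intercept-only model to each.  Participants
    with an empty subset are dropped and reported.  Returns a dict with keys
    ``ms``/``no_ms`` (FitResults), ``tables`` (the balanced tables) and
    ``dropped`` (participants excluded).
    """
    spec = spec or subset_spec()
    rng = np.random.default_rng(seed)
    free = df[df["num_blinks"] == 0]
    ms_all = free[free["ms_presence"].astype(bool)]
    no_all = free[~free["ms_presence"].astype(bool)]
    ms_rows, no_rows, dropped = [], [], []
    for pid in sorted(df["participant"].unique()):
        a = ms_all[ms_all["participant"] == pid]
        b = no_all[no_all["participant"] == pid]
        if len(a) == 0 or len(b) == 0:
            dropped.append(pid)
            continue
        n = min(len(a), len(b))
        if len(a) > n:
            a = a.iloc[rng.choice(len(a), size=n, replace=False)]
        if len(b) > n:
            b = b.iloc[rng.choice(len(b), size=n, replace=False)]
        ms_rows.append(a)
        no_rows.append(b)
    if not ms_rows:
        raise ValueError("no participant has trials in both subsets")
    ms_df = pd.concat(ms_rows, ignore_index=True)
    no_df = pd.concat(no_rows, ignore_index=True)
    return {
        "ms": fit_lmm(spec, ms_df),
        "no_ms": fit_lmm(spec, no_df),
        "tables": (ms_df, no_df),
        "dropped": dropped,
    }


def cortical_distance(eccentricity_deg):
    """Cortical distance (mm) of a visual-field eccentricity.

    ``d = ln(E) / 0.063 - 36.54``: millimetres of primary visual cortex from
    the retinotopic representation of 10 deg eccentricity (which maps to
    ~0 mm).  Strictly increasing; rejects non-positive eccentricities.
    """
    E = np.asarray(eccentricity_deg, dtype=float)
    if np.any(E <= 0):
        raise ValueError("eccentricity must be positive")
    d = np.log(E) / 0.063 - 36.54
    return float(d) if np.isscalar(eccentricity_deg) else d


def with_cortical_eccentricity(df: pd.DataFrame) -> pd.DataFrame:
    """Copy of ``df`` with eccentricity replaced by its cortical distance."""
    out = df.copy()
    out["eccentricity"] = cortical_distance(out["eccentricity"].to_numpy(float))
    return out
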