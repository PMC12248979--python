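"""Text-format readers/writers and the orchestrating pipeline.

Native formats are plain text: gaze traces as one TSV per trial (columns
``time_ms lx_deg ly_deg rx_deg ry_deg valid_l valid_r``), the trial table and
derived tables as CSV, configuration as YAML keyed by the dataclass field
names.  ``run_pipeline`` chains simulate -> detect -> metrics -> rate -> fit
and writes a run log with seeds, parameters and per-stage trial bookkeeping.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detect import DetectionParams, Microsaccade, detect_microsaccades, main_sequence
from .gaze import GazeTrace
from .metrics import summarize_trial
from .models import (
    ModelSpec,
    case_bootstrap,
    fit_lmm,
    immobilization_spec,
    ms_rate_spec,
    primary_ft_spec,
    subset_models,
    with_cortical_eccentricity,
)
from .rates import KernelParams, causal_rate, baseline_normalize
from .synth import GroundTruth, SimConfig, generate_experiment

log = logging.getLogger("fixfill")

TRACE_COLUMNS = ["time_ms", "lx_deg", "ly_deg", "rx_deg", "ry_deg", "valid_l", "valid_r"]


def write_gaze_tsv(trace: GazeTrace, path) -> None:
    df = pd.DataFrame({
        "time_ms": trace.time_ms,
        "lx_deg": trace.left[:, 0], "ly_deg": trace.left[:, 1],
        "rx_deg": trace.right[:, 0], "ry_deg": trace.right[:, 1],
        "valid_l": trace.valid_left.astype(int),
        "valid_r": trace.valid_right.astype(int),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_gaze_tsv(path, participant: str | None = None, trial: int | None = None) -> GazeTrace:
    """Read and validate a gaze trace TSV.

    Rejects missing columns (naming them) and non-uniform timestamps; the
    sampling rate is inferred from the timestamps.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} lacks columns: {missing}")
    t = df["time_ms"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("trace must hold at least 2 samples")
    dt = np.diff(t)
    if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-6):
        raise ValueError(f"non-uniform or non-increasing timestamps in {path}")
    fs = 1000.0 / dt[0]
    return GazeTrace(
        time_ms=t,
        left=df[["lx_deg", "ly_deg"]].to_numpy(float),
        right=df[["rx_deg", "ry_deg"]].to_numpy(float),
        valid_left=df["valid_l"].to_numpy(int).astype(bool),
        valid_right=df["valid_r"].to_numpy(int).astype(bool),
        sampling_rate=fs,
        participant=participant,
        trial=trial,
    )


def write_events_csv(events: list[Microsaccade], path, trial_ids: list[str] | None = None) -> None:
    rows = []
    for i, ev in enumerate(events):
        rows.append({
            "trial_id": trial_ids[i] if trial_ids else "",
            "participant": ev.participant,
            "trial": ev.trial,
            "onset_ms": ev.onset_ms,
            "offset_ms": ev.offset_ms,
            "amplitude_deg": ev.amplitude_deg,
            "peak_vel_deg_s": ev.peak_velocity,
            "direction_deg": ev.direction_deg,
        })
    pd.DataFrame(rows, columns=["trial_id", "participant", "trial", "onset_ms", "offset_ms",
                                "amplitude_deg", "peak_vel_deg_s", "direction_deg"]).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; YAML keys match field names."""

    out_dir: str = "fixfill_out"
    traces_dir: str | None = None
    trials_csv: str | None = None
    sim: SimConfig | None = field(default_factory=SimConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    kernel: KernelParams = field(default_factory=KernelParams)
    lambda_overrides: dict = field(default_factory=dict)  # participant -> multiplier
    n_boot: int = 0  # 0 disables bootstrap CIs in the report
    alpha: float = 0.05
    seed: int = 0
    cortical_eccentricity: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, klass in (("sim", SimConfig), ("detection", DetectionParams), ("kernel", KernelParams)):
            if isinstance(raw.get(key), dict):
                sub = dict(raw[key])
                if key == "sim" and "blocks" in sub:
                    sub["blocks"] = tuple(tuple(b) for b in sub["blocks"])
                raw[key] = klass(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, default_flow_style=None))


def _detect_all(traces: dict, params: DetectionParams, lambda_overrides: dict):
    events, larges = {}, {}
    for tid, trace in traces.items():
        p = params
        if trace.participant in lambda_overrides:
            p = dataclasses.replace(params, noise_multiplier=lambda_overrides[trace.participant])
        ev, lg = detect_microsaccades(trace, p)
        events[tid] = ev
        larges[tid] = lg
    return events, larges


def _metrics_table(trials: pd.DataFrame, traces: dict, events: dict, larges: dict) -> pd.DataFrame:
    rows = []
    for _, tr in trials.iterrows():
        tid = tr["trial_id"]
        m = summarize_trial(
            tid, tr["participant"], tr["ft_ms"] / 1000.0,
            traces[tid], events[tid], larges[tid],
        )
        row = dataclasses.asdict(m)
        row["exclusion_reason"] = m.exclusion_reason.value
        for k in ("block", "trial_num", "contrast", "eccentricity"):
            row[k] = tr[k]
        rows.append(row)
    return pd.DataFrame(rows)


def _fit_tables(metrics: pd.DataFrame, cfg: PipelineConfig) -> dict:
    """Fit the model family on retained trials; returns name -> table."""
    kept = metrics[~metrics["excluded"]].copy()
    kept["ms_presence"] = kept["ms_presence"].astype(int)
    kept["ocular_drift"] = kept["mean_drift"]
    if cfg.cortical_eccentricity:
        kept = with_cortical_eccentricity(kept)
    out = {}

    def table(spec: ModelSpec, data: pd.DataFrame, name: str) -> None:
        fit = fit_lmm(spec, data)
        rows = {t: {"parameter": t, "estimate": b, "ci_low": math.nan,
                    "ci_high": math.nan, "significant": ""} for t, b in fit.estimates.items()}
        if cfg.n_boot > 0:
            bs = case_bootstrap(spec, data, n_boot=cfg.n_boot, alpha=cfg.alpha, seed=cfg.seed)
            for t, (lo, hi) in bs.ci.items():
                rows[t].update(ci_low=lo, ci_high=hi,
                               significant="*" if (t != "intercept" and bs.significant[t]) else "")
        out[name] = pd.DataFrame(rows.values())

    table(primary_ft_spec(), kept, "ft_primary")

    rate_df = kept[kept["ms_count"] > 0].copy()
    rate_df["log_ms_rate"] = np.log(rate_df["ms_rate"])
    table(ms_rate_spec(), rate_df, "ms_rate")

    immo = kept[np.isfinite(kept["immobilization_ms"])].copy()
    immo["log_immobilization"] = np.log(immo["immobilization_ms"])
    immo["ms_amplitude"] = immo["last_ms_amplitude"]
    if len(immo):
        table(immobilization_spec(), immo, "immobilization")

    try:
        sub = subset_models(kept, seed=cfg.seed)
        for key in ("ms", "no_ms"):
            fit = sub[key]
            out[f"subset_{key}"] = pd.DataFrame(
                [{"parameter": t, "estimate": b} for t, b in fit.estimates.items()])
    except ValueError as exc:
        log.warning("subset models skipped: %s", exc)
    return out


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages and write a report directory; returns its path.

    Trial bookkeeping is conserved at every stage (input = retained + sum of
    exclusions by reason) and recorded in ``run_log.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"seed": cfg.seed, "stages": {}}

    # --- stage 1: obtain traces -------------------------------------------
    if cfg.traces_dir is not None:
        tdir = Path(cfg.traces_dir)
        if not tdir.is_dir():
            raise FileNotFoundError(f"traces dir not found: {tdir}")
        if cfg.trials_csv is None:
            raise ValueError("trials_csv required when reading traces from disk")
        trials = pd.read_csv(cfg.trials_csv)
        traces = {tid: read_gaze_tsv(tdir / f"{tid}.tsv",
                                     participant=str(pid), trial=int(tn))
                  for tid, pid, tn in zip(trials["trial_id"], trials["participant"],
                                          trials["trial_num"])}
        run_log["stages"]["load"] = {"n_trials": len(trials)}
    else:
        if cfg.sim is None:
            raise ValueError("either traces_dir or a sim config must be given")
        trials, traces, _truth = generate_experiment(cfg.sim, GroundTruth(), seed=cfg.seed)
        trials.to_csv(out / "trials.csv", index=False)
        run_log["stages"]["simulate"] = {"n_trials": len(trials), "seed": cfg.seed}
    log.info("stage traces: %d trials", len(trials))

    # --- stage 2: detection ------------------------------------------------
    events, larges = _detect_all(traces, cfg.detection, cfg.lambda_overrides)
    flat, tids = [], []
    for tid, evs in events.items():
        flat.extend(evs)
        tids.extend([tid] * len(evs))
    write_events_csv(flat, out / "events.csv", tids)
    run_log["stages"]["detect"] = {
        "n_events": len(flat),
        "n_large_saccades": int(sum(len(v) for v in larges.values())),
    }
    if len(flat) >= 10:
        slope, r = main_sequence(flat)
        run_log["stages"]["detect"]["main_sequence_loglog_slope"] = slope
        run_log["stages"]["detect"]["main_sequence_correlation"] = r

    # --- stage 3: metrics & exclusions ------------------------------------
    metrics = _metrics_table(trials, traces, events, larges)
    metrics.to_csv(out / "metrics.csv", index=False)
    reason_counts = metrics["exclusion_reason"].value_counts().to_dict()
    n_kept = int((~metrics["excluded"]).sum())
    if n_kept + sum(v for k, v in reason_counts.items() if k != "none") != len(trials):
        raise RuntimeError("trial bookkeeping failure: counts do not reconcile")
    run_log["stages"]["metrics"] = {"n_trials": len(metrics), "n_retained": n_kept,
                                    "excluded_by_reason": {k: int(v) for k, v in reason_counts.items()
                                                           if k != "none"}}

    # --- stage 4: rate dynamics -------------------------------------------
    peri_ms = 2000.0
    rate_rows = []
    curves = {}
    for pid, grp in metrics[~metrics["excluded"]].groupby("participant"):
        onsets, durs = [], []
        for _, row in grp.iterrows():
            tid = row["trial_id"]
            press = row["ft_s"] * 1000.0
            bl = traces[tid].blink_intervals()
            near_press = any(off >= press - peri_ms for _, off in bl) or any(
                ev.offset_ms >= press - peri_ms for ev in larges[tid])
            if near_press:
                continue
            onsets.append(np.array([ev.onset_ms - press for ev in events[tid]]))
            durs.append(press)
        if onsets:
            curves[pid] = causal_rate(onsets, durs, cfg.kernel,
                                      t_grid=np.arange(-8000.0, 1.0))
    if curves:
        normed, omitted = baseline_normalize(curves)
        for pid, c in normed.items():
            for t, r_, n_ in zip(c.time_ms, c.rate, c.n_trials):
                rate_rows.append((pid, t, r_, int(n_)))
        pd.DataFrame(rate_rows, columns=["participant", "time_ms", "rate_hz", "n_trials"]).to_csv(
            out / "rates.csv", index=False)
        run_log["stages"]["rate"] = {"n_participants": len(normed),
                                     "omitted_zero_baseline": omitted}

    # --- stage 5: models ---------------------------------------------------
    tables = _fit_tables(metrics, cfg)
    for name, tab in tables.items():
        tab.to_csv(out / f"model_{name}.csv", index=False)
    run_log["stages"]["fit"] = {"models": sorted(tables), "n_boot": cfg.n_boot}

    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    return out
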