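"""Fit the primary filling-in-time mixed model with bootstrap intervals.

Generates a mid-sized synthetic experiment from the published coefficient
structure, fits the primary log-FT model (REML, random intercept + slopes)
and derives Bonferroni-corrected percentile confidence intervals by
resampling participants with replacement.
"""

from fixfill import SimConfig, case_bootstrap, fit_lmm, generate_experiment, primary_ft_spec

cfg = SimConfig(n_participants=12, trials_per_block=10, seed=8)
trials, _, truth = generate_experiment(cfg, seed=8, with_traces=False)
df = trials.copy()
df["log_ft"] = df["log_ft_true"]  # outcome on the model scale

spec = primary_ft_spec()
fit = fit_lmm(spec, df)
boot = case_bootstrap(spec, df, n_boot=100, alpha=0.05, seed=8)

print(f"n = {fit.n_obs} trials, {df.participant.nunique()} participants, "
      f"converged = {fit.converged}")
print(f"per-term CI level: {100 * (1 - boot.alpha_corrected):.1f}% "
      f"(alpha 0.05 Bonferroni-corrected across {len(boot.terms) - 1} terms)")
print(f"{'term':28s} {'injected':>9} {'fitted':>8}   bootstrap CI")
for term, est in fit.estimates.items():
    lo, hi = boot.ci[term]
    star = "*" if term != "intercept" and boot.significant[term] else " "
    inj = truth.fixed_effects.get(term, 0.0)
    if term == "intercept":
        inj += truth.ft_log_offset  # generator maps the model scale to seconds
    print(f"{term:28s} {inj:+9.3f} {est:+8.3f}  [{lo:+.3f}, {hi:+.3f}]{star}")

# Starred terms have corrected intervals excluding zero; fitted values track
# the injected coefficients within sampling error at this reduced size.
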