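"""Press-aligned microsaccade rate with a causal kernel.

Pools microsaccade onsets across synthetic trials, aligned to the report
(press = 0), smooths them with the one-sided kernel and shows the pre-report
dip: the generator suppresses events in the last 600 ms before the report,
and the causal rate estimate recovers that suppression.
"""

import numpy as np

from fixfill import GroundTruth, KernelParams, SimConfig, causal_rate, generate_experiment

cfg = SimConfig(n_participants=6, trials_per_block=4, blink_rate=0.0, seed=21)
trials, _, truth = generate_experiment(cfg, GroundTruth(), seed=21, with_traces=False)

onsets, durations = [], []
for _, row in trials.iterrows():
    press = row["ft_ms"]
    evs = truth.injected_events[row["trial_id"]]
    onsets.append(np.array([ev.onset_s * 1000.0 - press for ev in evs]))
    durations.append(press)

curve = causal_rate(onsets, durations, KernelParams(), t_grid=np.arange(-8000.0, 1.0))
dip_win = (curve.time_ms >= -1000) & (curve.time_ms <= 0)
dip = curve.rate[dip_win].min()

print(f"trials: {len(onsets)}, events pooled: {sum(len(o) for o in onsets)}")
print(f"baseline rate (-5 to -3 s before report): {curve.baseline:.2f} Hz")
print(f"minimum rate in the last second        : {dip:.2f} Hz "
      f"({100 * dip / curve.baseline:.0f}% of baseline)")

# The baseline sits near the task's ~0.9 Hz microsaccade rate; the final-second
# minimum falls well below it — fixation stabilizes just before filling-in.
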