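"""Simulate a binocular gaze trace and detect its microsaccades.

Builds a 10-s fixation trace with ocular drift, measurement noise and four
injected microsaccades on the main sequence, then runs the binocular
velocity-threshold detector and compares detections against the injected
ground truth.
"""

import numpy as np

from fixfill import SimConfig, detect_microsaccades, generate_trace
from fixfill.synth import InjectedEvent

cfg = SimConfig(blink_rate=0.0)
events = [
    InjectedEvent(onset_s=2.0, amplitude_deg=0.10, direction_deg=30.0),
    InjectedEvent(onset_s=4.5, amplitude_deg=0.25, direction_deg=200.0),
    InjectedEvent(onset_s=6.0, amplitude_deg=0.50, direction_deg=90.0),
    InjectedEvent(onset_s=8.2, amplitude_deg=0.75, direction_deg=315.0),
]
trace = generate_trace(10.0, events, [], cfg, seed=1)
micro, large = detect_microsaccades(trace)

print(f"injected {len(events)} microsaccades, detected {len(micro)} "
      f"(+{len(large)} large saccades)")
print(f"{'onset true':>11} {'onset det':>10} {'amp true':>9} {'amp det':>8} {'peak v':>7}")
for ev in events:
    hit = min(micro, key=lambda m: abs(m.onset_ms - ev.onset_s * 1000))
    print(f"{ev.onset_s*1000:10.0f}ms {hit.onset_ms:9.0f}ms "
          f"{ev.amplitude_deg:8.3f}° {hit.amplitude_deg:7.3f}° "
          f"{hit.peak_velocity:5.1f}°/s")

# Peak velocity grows with amplitude (the main sequence); onsets land within
# ~10 ms of truth (the 31-ms estimation window slightly anticipates onsets),
# and amplitudes are read back from the gaze path itself.
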