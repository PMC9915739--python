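"""Calcium event detection on simulated dF/F traces.

Generates noisy traces with isolated kernel-shaped transients at known
times, runs the derivative-based event detector (5-SD derivative rule, 3-SD
peak rule), and reports recall, precision and magnitude recovery against
the ground truth.
"""
import numpy as np

import mesoframe as mf
from mesoframe.synthetic import simulate_event_traces

noise_sd = 0.05
traces, truth = simulate_event_traces(
    50, duration_s=480.0, noise_sd=noise_sd,
    amplitude_range=(6 * noise_sd, 12 * noise_sd), rate_hz=0.05, seed=2,
)

tp = fp = fn = 0
mag_errors = []
for i, tr in enumerate(traces):
    stats = mf.estimate_baseline_stats(tr, fs=30.0)
    events = mf.detect_events(tr, fs=30.0, stats=stats)
    remaining = list(truth.event_frames[i])
    amps = dict(zip(truth.event_frames[i], truth.event_amplitudes[i]))
    for ev in events:
        hit = [t for t in remaining if ev.start_frame - 6 <= t <= ev.end_frame]
        if hit:
            remaining.remove(hit[0])
            tp += 1
            mag_errors.append(ev.magnitude - amps[hit[0]])
        else:
            fp += 1
    fn += len(remaining)

print(f"events: {tp} matched, {fp} false, {fn} missed")
print(f"recall {tp/(tp+fn):.3f}, precision {tp/(tp+fp):.3f}")
print(f"magnitude error: {np.mean(mag_errors):+.4f} dF/F "
      f"(injected amplitudes {6*noise_sd:.2f}-{12*noise_sd:.2f})")
print("Recall/precision near 1 means the 5-SD derivative + 3-SD peak rules "
      "recover nearly every transient whose peak clears 6 noise SDs.")
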