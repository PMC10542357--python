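"""Threshold-crossing latency on a noiseless line-scan trace.

A GCaMP6s-like transient (saturating rise, time constant 20 ms, peak dF/F
1.0) starting 37.9 ms or 67.9 ms after the stimulus crosses the 10% level
at 20*ln(10/9) ~ 2.107 ms after its onset, so the interpolated latencies
land at 40.0 and 70.0 ms.
"""

from evoked2p import (
    SceneConfig,
    compute_dff,
    estimate_latency,
    simulate_traces,
    trial_baseline,
)

STIM_MS = 1_000.0

for onset_post in (37.9, 67.9):
    cfg = SceneConfig(n_rois=1, sample_period_ms=1.0, duration_ms=3_000.0,
                      onsets_ms=[STIM_MS], amplitudes=1.0, latency=onset_post,
                      tau_r=20.0, tau_d=None, noise_sigma_frac=0.0)
    traces, _ = simulate_traces(cfg)
    f0, truncated = trial_baseline(traces.values[0], traces.times, STIM_MS)
    dff = compute_dff(traces.values[0], f0, times=traces.times)
    lat = estimate_latency(dff, onset=STIM_MS, response_window=500.0,
                           threshold=0.10, min_consecutive=5, interpolate=True)
    print(f"transient onset {onset_post:5.1f} ms post-stimulus "
          f"-> 10%-crossing latency {lat:.3f} ms (baseline F0={f0:.2f})")

print("\nLatency = time from stimulus onset to the interpolated instant the")
print("dF/F trace reaches 10% above its trial baseline.")
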