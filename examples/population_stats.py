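"""Population readouts: responder fractions, latency modes, speed advantage.

Simulates a strongly responsive layer-5-like population (exponential peak
dF/F amplitudes, mean 0.072) and a weakly responsive layer-4-like one
(mean 0.0334) across 7 fields of view, classifies responders at the 10%
threshold, then compares a bimodal 40/70 ms latency sample against a
unimodal 70 ms one.
"""

import numpy as np
import pandas as pd

from evoked2p import (
    LatencyMixture,
    SceneConfig,
    TrialSpec,
    compare_latency_populations,
    detect_response,
    latency_modes,
    per_trial_dff,
    responder_fraction,
    simulate_latencies,
    simulate_traces,
)

ONSETS = [11_000.0, 24_000.0, 37_000.0]

rows = []
for pop, amp_mean, seed0 in [("layer5", 0.072, 1), ("layer4", 0.0334, 11)]:
    for k in range(7):
        cfg = SceneConfig(n_rois=40, sample_period_ms=33.3,
                          duration_ms=ONSETS[-1] + 3_000.0, onsets_ms=ONSETS,
                          amplitude_exponential_mean=amp_mean, latency=40.0,
                          noise_sigma_frac=0.02, seed=seed0 + k)
        traces, _ = simulate_traces(cfg)
        trials = TrialSpec(onsets=ONSETS, response_window=2_000.0)
        for d in per_trial_dff(traces, trials):
            onset = trials.onsets[trials.trial_ids.index(d.trial_id)]
            call = detect_response(d, onset=onset, response_window=2_000.0)
            rows.append({"population": pop, "field": f"{pop}_f{k}",
                         "roi_id": d.roi_id, "trial_id": d.trial_id,
                         "responsive": call.responsive})

for pop, st in responder_fraction(pd.DataFrame(rows)).items():
    print(f"{pop}: {100 * st.responder_fraction:.1f}% responders "
          f"(+/- {100 * st.sem:.1f}% SEM across {len(st.field_fractions)} fields, "
          f"{st.n_responsive}/{st.n_rois} ROIs)")

fast = simulate_latencies(LatencyMixture([40.0, 70.0], [0.68, 0.32], sigma=2.0), 92, 42)
slow = simulate_latencies(LatencyMixture([70.0], [1.0], sigma=2.0), 39, 43)

m_fast = latency_modes(fast, bandwidth=5.0)
m_slow = latency_modes(slow, bandwidth=5.0)
print(f"\nfast population latency modes: {m_fast.modes} ms (n=92)")
print(f"slow population latency modes: {m_slow.modes} ms (n=39)")

cmp = compare_latency_populations(fast, slow)
print(f"\nmean latency {cmp['mean_a']:.1f} vs {cmp['mean_b']:.1f} ms -> "
      f"{cmp['percent_reduction']:.1f}% faster")
print(f"K-S: D={cmp['ks'].statistic:.3f}, p={cmp['ks'].pvalue:.2e}")
print("\nThe bimodal population carries an early 40 ms latency component the")
print("unimodal one lacks, which shows up as a ~29% shorter mean latency and")
print("a significant K-S separation of the two latency distributions.")
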