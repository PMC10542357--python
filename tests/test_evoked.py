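"""Evoked-response detection, latency, fold change and population stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from evoked2p import (
    LatencyMixture,
    SceneConfig,
    compare_latency_populations,
    compute_dff,
    detect_response,
    estimate_latency,
    fold_change,
    ks_two_sample,
    latency_modes,
    responder_fraction,
    simulate_latencies,
    simulate_traces,
    trial_baseline,
)

from conftest import make_dff


def synth_dff(onset_post_stim, amplitude=1.0, stim=1_000.0, period=1.0,
              duration=3_000.0, tau_d=None, noise=0.0, seed=0):
    """Full-path dF/F for one transient: simulate -> baseline -> normalize."""
    cfg = SceneConfig(n_rois=1, sample_period_ms=period, duration_ms=duration,
                      onsets_ms=[stim], amplitudes=amplitude,
                      latency=onset_post_stim, tau_r=20.0, tau_d=tau_d,
                      noise_sigma_frac=noise, seed=seed)
    traces, _ = simulate_traces(cfg)
    f0, _ = trial_baseline(traces.values[0], traces.times, stim)
    return compute_dff(traces.values[0], f0, times=traces.times), stim


class TestDetectResponse:
    def test_clear_transient_is_responsive(self):
        d, stim = synth_dff(40.0, amplitude=0.3)
        call = detect_response(d, onset=stim, response_window=500.0, min_consecutive=5)
        assert call.responsive
        assert call.peak_dff == pytest.approx(0.3, abs=1e-6)
        assert call.latency_ms is not None

    def test_small_transient_not_responsive(self):
        d, stim = synth_dff(40.0, amplitude=0.05)
        call = detect_response(d, onset=stim, response_window=500.0, min_consecutive=5)
        assert not call.responsive
        assert call.latency_ms is None
        assert call.peak_dff == pytest.approx(0.05, abs=1e-6)

    def test_masked_window_indeterminate(self):
        t = np.arange(0.0, 3_000.0, 33.3)
        d = make_dff(t, np.zeros(t.shape), valid=(t <= 1_000.0))
        call = detect_response(d, onset=1_000.0, response_window=2_000.0)
        assert call.indeterminate and not call.responsive

    def test_min_consecutive_guards_single_blip(self):
        t = np.arange(0.0, 2_000.0, 33.3)
        dff = np.zeros(t.shape)
        dff[40] = 0.5  # one isolated supra-threshold sample
        call = detect_response(make_dff(t, dff), onset=1_000.0,
                               response_window=900.0, min_consecutive=2)
        assert not call.responsive


class TestLatency:
    @pytest.mark.parametrize("onset_post, expected", [(37.9, 40.0), (67.9, 70.0)])
    def test_closed_form_crossing(self, onset_post, expected):
        """Saturating rise (tau_r 20 ms, peak 1.0) crosses 0.10 at
        onset + 20*ln(10/9) ~ onset + 2.107 ms."""
        d, stim = synth_dff(onset_post)
        lat = estimate_latency(d, onset=stim, response_window=500.0,
                               min_consecutive=5, interpolate=True)
        assert lat == pytest.approx(expected, abs=0.1)

    def test_first_sample_rule(self):
        d, stim = synth_dff(37.9)
        lat = estimate_latency(d, onset=stim, response_window=500.0,
                               min_consecutive=5, interpolate=False)
        # first sample at/above threshold is the 41 ms sample post-stimulus
        assert lat == pytest.approx(41.0, abs=1e-9)

    def test_no_crossing_returns_none(self):
        d, stim = synth_dff(40.0, amplitude=0.05)
        assert estimate_latency(d, onset=stim, response_window=500.0,
                                min_consecutive=5) is None

    @pytest.mark.parametrize("delta", [5.0, 17.0, 50.0])
    def test_monotone_in_onset_shift(self, delta):
        """Shifting the transient later by delta shifts latency by delta."""
        d0, stim = synth_dff(37.9)
        d1, _ = synth_dff(37.9 + delta)
        l0 = estimate_latency(d0, onset=stim, response_window=500.0, min_consecutive=5)
        l1 = estimate_latency(d1, onset=stim, response_window=500.0, min_consecutive=5)
        assert l1 - l0 == pytest.approx(delta, abs=1e-6)

    def test_invariant_to_fluorescence_gain(self):
        """Threshold is relative, so rescaling raw F leaves latency fixed."""
        cfg = SceneConfig(n_rois=1, sample_period_ms=1.0, duration_ms=3_000.0,
                          onsets_ms=[1_000.0], amplitudes=1.0, latency=37.9,
                          tau_d=None, noise_sigma_frac=0.0)
        traces, _ = simulate_traces(cfg)
        lats = []
        for gain in (1.0, 3.7, 0.2):
            f = gain * traces.values[0]
            f0, _ = trial_baseline(f, traces.times, 1_000.0)
            d = compute_dff(f, f0, times=traces.times)
            lats.append(estimate_latency(d, onset=1_000.0, response_window=500.0,
                                         min_consecutive=5))
        assert lats[0] == pytest.approx(lats[1]) == pytest.approx(lats[2])


class TestFoldChange:
    def test_identical_windows(self):
        t = np.arange(100.0)
        v = np.full(100, 50.0)
        assert fold_change(v, t, (0, 50), (50, 100)) == pytest.approx(1.0)

    def test_forty_percent_step(self):
        t = np.arange(100.0)
        v = np.where(t < 50, 100.0, 140.0)
        assert fold_change(v, t, (0, 50), (50, 100)) == pytest.approx(1.4)

    def test_noisy_plateau_recovery(self):
        rng = np.random.default_rng(7)
        t = np.arange(400.0)
        v = np.where(t < 200, 100.0, 140.0) + 2.0 * rng.standard_normal(400)
        assert fold_change(v, t, (0, 200), (200, 400)) == pytest.approx(1.40, abs=0.01)

    def test_nonpositive_pre_mean_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            fold_change(np.zeros(10), t, (0, 5), (5, 10))


class TestResponderFraction:
    @staticmethod
    def calls(flags, field="f0", pop="p", n_trials=1):
        return pd.DataFrame([
            {"population": pop, "field": field, "roi_id": f"r{i}",
             "trial_id": f"t{j}", "responsive": bool(flag)}
            for i, flag in enumerate(flags) for j in range(n_trials)
        ])

    def test_all_responsive(self):
        st = responder_fraction(self.calls([True] * 5))["p"]
        assert st.responder_fraction == pytest.approx(1.0)

    def test_one_in_twenty(self):
        st = responder_fraction(self.calls([True] + [False] * 19))["p"]
        assert st.responder_fraction == pytest.approx(0.05)

    def test_majority_rule(self):
        rows = []
        for j, resp in enumerate([True, True, False]):     # 2/3 -> responsive
            rows.append({"population": "p", "field": "f0", "roi_id": "a",
                         "trial_id": f"t{j}", "responsive": resp})
        for j, resp in enumerate([True, False, False]):    # 1/3 -> not
            rows.append({"population": "p", "field": "f0", "roi_id": "b",
                         "trial_id": f"t{j}", "responsive": resp})
        st = responder_fraction(pd.DataFrame(rows))["p"]
        assert st.responder_fraction == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            responder_fraction(pd.DataFrame(columns=["population", "field",
                                                     "roi_id", "responsive"]))

    def test_unbiased_over_seeded_simulations(self):
        """Grand-mean fraction over 200 seeded Bernoulli simulations lies
        within the 95% binomial band around the true responder rate."""
        p_true, n_sims, n_fields, n_rois = 0.3, 200, 5, 20
        rng = np.random.default_rng(2024)
        grand = []
        for _ in range(n_sims):
            flags = rng.random((n_fields, n_rois)) < p_true
            df = pd.concat([self.calls(flags[f], field=f"f{f}") for f in range(n_fields)])
            grand.append(responder_fraction(df)["p"].responder_fraction)
        n_total = n_sims * n_fields * n_rois
        band = 1.96 * np.sqrt(p_true * (1 - p_true) / n_total)
        assert abs(np.mean(grand) - p_true) < band


class TestLatencyModes:
    def test_single_point_mass(self):
        m = latency_modes([70.0] * 10, bandwidth=5.0)
        assert m.modes == [70.0]

    def test_bimodal_recovery(self):
        lat = simulate_latencies(LatencyMixture([40.0, 70.0], [0.6, 0.4], sigma=3.0),
                                 92, seed=5)
        m = latency_modes(lat, bandwidth=5.0)
        assert len(m.modes) == 2
        assert m.modes[0] == pytest.approx(40.0, abs=3.0)
        assert m.modes[1] == pytest.approx(70.0, abs=3.0)

    def test_unimodal_recovery(self):
        lat = simulate_latencies(LatencyMixture([70.0], [1.0], sigma=3.0), 39, seed=6)
        m = latency_modes(lat, bandwidth=5.0)
        assert len(m.modes) == 1
        assert m.modes[0] == pytest.approx(70.0, abs=3.0)

    def test_mode_recovery_rate(self):
        """Well-separated mixture (>= 4 sigma): both modes recovered within
        one bandwidth in at least 90% of seeded runs."""
        hits = 0
        runs = 30
        for seed in range(runs):
            lat = simulate_latencies(
                LatencyMixture([40.0, 70.0], [0.6, 0.4], sigma=3.0), 92, seed=seed)
            m = latency_modes(lat, bandwidth=5.0)
            if (len(m.modes) == 2 and abs(m.modes[0] - 40) <= 5.0
                    and abs(m.modes[1] - 70) <= 5.0):
                hits += 1
        assert hits / runs >= 0.9

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            latency_modes([1.0, 2.0, 3.0], bandwidth=5.0)

    def test_modes_sorted_and_strict_maxima(self):
        lat = simulate_latencies(LatencyMixture([30.0, 80.0], [0.5, 0.5], sigma=4.0),
                                 100, seed=9)
        m = latency_modes(lat, bandwidth=5.0)
        assert m.modes == sorted(m.modes)
        for mode in m.modes:
            i = int(np.flatnonzero(m.grid == mode)[0])
            assert m.density[i] > m.density[i - 1] and m.density[i] > m.density[i + 1]


def bruteforce_ks(a, b):
    """Independent oracle: sup of |ECDF difference| over every step point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        best = max(best, abs((a <= x).mean() - (b <= x).mean()))
    return best


class TestKs:
    def test_identical_samples(self):
        r = ks_two_sample([1.0, 2.0], [1.0, 2.0])
        assert r.statistic == 0.0

    def test_disjoint_singletons(self):
        assert ks_two_sample([0.0], [1.0]).statistic == 1.0

    def test_interleaved_thirds(self):
        r = ks_two_sample([1, 2, 3], [1.5, 2.5, 3.5])
        assert r.statistic == pytest.approx(1 / 3)

    def test_matches_bruteforce_oracle_small_samples(self):
        """D equals the exhaustive step-point oracle on all sampled pairs of
        sizes <= 12."""
        rng = np.random.default_rng(77)
        for _ in range(200):
            na, nb = rng.integers(1, 13, size=2)
            a = np.round(rng.normal(0, 1, na), 1)   # ties are likely
            b = np.round(rng.normal(0.3, 1, nb), 1)
            assert ks_two_sample(a, b).statistic == pytest.approx(bruteforce_ks(a, b))

    def test_matches_scipy(self):
        """D agrees with scipy exactly; the plain asymptotic p agrees with
        scipy's exact p to the accuracy expected of the limit distribution
        at moderate p and n ~ 40-50."""
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0.25, 1, 40)
        mine = ks_two_sample(a, b)
        ref = sps.ks_2samp(a, b, method="exact")
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.pvalue == pytest.approx(ref.pvalue, rel=0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestComparePopulations:
    def test_identical_samples(self):
        r = compare_latency_populations([40.0, 70.0], [40.0, 70.0])
        assert r["percent_reduction"] == pytest.approx(0.0)
        assert r["ks"].statistic == 0.0

    def test_exact_mixture_arithmetic(self):
        """68:32 two-point mixture at 40/70 ms vs pure 70 ms: mean 49.6 ms,
        29.1% reduction."""
        a = [40.0] * 68 + [70.0] * 32
        b = [70.0] * 39
        r = compare_latency_populations(a, b)
        assert r["mean_a"] == pytest.approx(49.6)
        assert r["percent_reduction"] == pytest.approx(100 * (70 - 49.6) / 70, abs=1e-9)

    def test_half_reduction(self):
        r = compare_latency_populations([35.0] * 5, [70.0] * 5)
        assert r["percent_reduction"] == pytest.approx(50.0)

    def test_zero_reference_mean_rejected(self):
        with pytest.raises(ValueError):
            compare_latency_populations([1.0], [0.0])
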