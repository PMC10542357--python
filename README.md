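# evoked2p

Analysis of stimulus-evoked two-photon calcium imaging from awake,
head-fixed mice, plus the deterministic scoring rules for the companion
nociceptive behavior assays. The package targets experiments in which
somatosensory/motor cortex neurons expressing GCaMP6s are imaged while
brief electrical stimuli are delivered to the hindpaw, and the questions
are *which* cells respond, *how fast*, and whether two populations (e.g.
layer 5 spino-cortical recipient neurons vs layer 4 thalamo-recipient
neurons) differ in responder fraction and latency structure.

It is a library first (`import evoked2p`), with narrative scripts under
`examples/` and a thin `evoked2p` CLI for shell use.

## What it computes

- **Rigid motion correction.** Each frame is realigned to a reference
  image (the average of the stable frames) by the integer translation
  maximizing the zero-normalized cross-correlation, searched exhaustively
  over `[-max_shift, max_shift]²`. Borders exposed by the shift are marked
  invalid, never zero-filled into ROI averages.
- **ΔF/F.** For ROI fluorescence `F(t)` and a per-trial baseline
  `F₀` (mean of the 10 s before each stimulus onset, half-open window),
  activity is `ΔF/F = (F − F₀)/F₀`.
- **Evoked-response detection and latency.** A cell responds to a trial
  when ΔF/F holds at or above 10% of baseline for at least
  `min_consecutive` samples in the post-stimulus window. The response
  latency is the time from stimulus onset to the (linearly interpolated)
  10% crossing. For a saturating-rise transient
  `ΔF/F(t) = A·(1 − e^{−(t−L)/τ_r})`, the crossing sits at
  `L + τ_r·ln(1/(1 − 0.1/A))` — e.g. 40.0 ms for `L = 37.9 ms`,
  `τ_r = 20 ms`, `A = 1`.
- **Population statistics.** Responder fractions per field of view
  (majority rule across trials, mean ± SEM across fields), latency
  distribution modes from a Gaussian KDE on a 1-ms grid, percent
  reduction in mean latency `100·(μ_b − μ_a)/μ_b`, and the two-sample
  Kolmogorov–Smirnov comparison `D = sup|ECDF_a − ECDF_b|` with the
  asymptotic p-value at effective `n = n_a n_b/(n_a + n_b)`.
- **Behavior scoring.** von Frey mechanical threshold (lowest filament
  force with withdrawal on ≥ 3 of 5 applications), foot-shock escape
  latency (first escape frame / 30 fps), and protective-cutoff censoring
  (Hargreaves 20 s, hot plate 30 s, beam 60 s).
- **Synthetic data with ground truth.** Seeded generators for movies,
  traces, latency samples and behavior tables that emulate the study's
  statistical structure (GCaMP6s-like kinetics, bimodal 40/70 ms vs
  unimodal 70 ms latencies, responder fractions set by an exponential
  peak-amplitude distribution meeting the 10% threshold, rigid jitter,
  additive Gaussian noise).

## Worked example

```sh
python examples/population_stats.py
```

prints (exactly, for the seeds baked into the script):

```
layer4: 7.1% responders (+/- 1.6% SEM across 7 fields, 20/280 ROIs)
layer5: 26.1% responders (+/- 2.4% SEM across 7 fields, 73/280 ROIs)

fast population latency modes: [40.0, 70.0] ms (n=92)
slow population latency modes: [70.0] ms (n=39)

mean latency 49.6 vs 70.2 ms -> 29.3% faster
K-S: D=0.728, p=4.83e-13
```

The layer-5-like population (exponential peak ΔF/F, mean 0.072) clears
the 10% detection threshold about five times as often as the
layer-4-like one (mean 0.0334); the bimodal latency sample shows the
40 ms and 70 ms modes, the unimodal sample only 70 ms; and the early
component makes the fast population ~29% quicker on mean latency, a
difference the K–S test resolves decisively.

Other examples: `register_movie.py` (exact recovery of a known jitter
path), `evoked_latency.py` (closed-form 40.0/70.0 ms crossings),
`behavior_scoring.py`, `full_pipeline.py` (synthetic movie through
register → extract → evoked, report vs truth).

## CLI

```sh
evoked2p register --in movie.tif --out reg.tif --shifts shifts.csv --max-shift 20
evoked2p extract --movie reg.tif --rois rois.tif --trials trials.csv --out traces.csv
evoked2p evoked --dff dff.csv --trials trials.csv --out report.json
evoked2p behavior score --assay vonfrey --in vf.csv --out thresholds.csv
evoked2p simulate traces --seed 7 --out sim/
evoked2p pipeline --config run.yaml
```

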