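"""Stimulus-evoked response detection, latency and population statistics.

A cell counts as responding to a trial when its dF/F reaches 10% above
baseline (threshold 0.10) for at least ``min_consecutive`` samples inside
the post-stimulus response window.  The response latency is the time from
stimulus onset to the threshold crossing, linearly interpolated between the
last sub-threshold and first supra-threshold samples (sub-sample accuracy
matters at 33.3 ms frames; line scans at ~1 ms barely need it).

Population readouts: responder fractions per field of view (majority rule
across trials), latency-distribution modes from a Gaussian-kernel density
on a 1-ms grid, percent reduction in mean latency between populations, and
the two-sample Kolmogorov-Smirnov comparison of latency distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from .traces import DffTrace, TrialSpec

DEFAULT_THRESHOLD = 0.10
DEFAULT_MIN_CONSECUTIVE_FRAME = 2
DEFAULT_MIN_CONSECUTIVE_LINE = 5
DEFAULT_KDE_BANDWIDTH_MS = 5.0
DEFAULT_PEAK_REL_FLOOR = 0.2


@dataclass
class ResponseCall:
    """Per-ROI, per-trial classification and latency."""

    roi_id: str
    trial_id: str
    responsive: bool
    latency_ms: float | None
    peak_dff: float
    threshold: float = DEFAULT_THRESHOLD
    indeterminate: bool = False

    def __post_init__(self) -> None:
        if self.responsive and self.latency_ms is None:
            raise ValueError("responsive call must carry a latency")
        if not self.responsive and self.latency_ms is not None:
            raise ValueError("non-responsive call must not carry a latency")


@dataclass
class PopulationStats:
    """Responder statistics for one population across fields of view."""

    label: str
    n_rois: int
    n_responsive: int
    field_fractions: list[float]
    responder_fraction: float
    sem: float
    latencies: list[float] = field(default_factory=list)
    mean_latency: float | None = None


@dataclass
class ModeEstimate:
    """Modes of a latency distribution from a Gaussian KDE on a 1-ms grid."""

    modes: list[float]
    bandwidth: float
    density_at_modes: list[float]
    grid: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    density: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass
class KsResult:
    """Two-sample Kolmogorov-Smirnov comparison."""

    statistic: float
    pvalue: float
    n_a: int
    n_b: int


def _window_indices(times: np.ndarray, onset: float, response_window: float) -> np.ndarray:
    return np.flatnonzero((times > onset) & (times <= onset + response_window))


def _first_qualifying_run(supra: np.ndarray, valid: np.ndarray, min_consecutive: int) -> int | None:
    """Index (into the window) of the first sample starting a run of
    >= min_consecutive consecutive valid supra-threshold samples."""
    run = 0
    for j in range(len(supra)):
        if valid[j] and supra[j]:
            run += 1
            if run >= min_consecutive:
                return j - run + 1
        else:
            run = 0
    return None


def detect_response(
    dff: DffTrace,
    trial: TrialSpec | None = None,
    onset: float | None = None,
    response_window: float | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE_FRAME,
    interpolate: bool = True,
) -> ResponseCall:
    """Classify one dF/F trace against one trial.

    Responsive iff the trace holds at/above ``threshold`` for at least
    ``min_consecutive`` consecutive valid samples inside
    ``(onset, onset + response_window]``.  ``peak_dff`` is always reported;
    a fully masked window yields an indeterminate, non-responsive call.
    """
    if onset is None:
        if trial is None or not trial.onsets:
            raise ValueError("need an onset (directly or via trial)")
        onset = trial.onsets[0]
    if response_window is None:
        response_window = trial.response_window if trial is not None else 2_000.0
    idx = _window_indices(dff.times, onset, response_window)
    if len(idx) < 2:
        raise ValueError("response window must contain >= 2 samples")
    v = dff.valid[idx]
    if not v.any():
        return ResponseCall(dff.roi_id, dff.trial_id, responsive=False,
                            latency_ms=None, peak_dff=np.nan,
                            threshold=threshold, indeterminate=True)
    d = dff.dff[idx]
    peak = float(np.max(d[v]))
    start = _first_qualifying_run(d >= threshold, v, min_consecutive)
    if start is None:
        return ResponseCall(dff.roi_id, dff.trial_id, responsive=False,
                            latency_ms=None, peak_dff=peak, threshold=threshold)
    latency = estimate_latency(dff, onset=onset, response_window=response_window,
                               threshold=threshold, min_consecutive=min_consecutive,
                               interpolate=interpolate)
    return ResponseCall(dff.roi_id, dff.trial_id, responsive=True,
                        latency_ms=latency, peak_dff=peak, threshold=threshold)


def estimate_latency(
    dff: DffTrace,
    trial: TrialSpec | None = None,
    onset: float | None = None,
    response_window: float | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE_FRAME,
    interpolate: bool = True,
) -> float | None:
    """Threshold-crossing latency in ms, or ``None`` if no crossing.

    The crossing sample is the first sample of the first qualifying run
    (so isolated noise blips shorter than ``min_consecutive`` are skipped).
    With ``interpolate`` the latency is the linearly interpolated time at
    which the trace reaches the threshold between the preceding valid
    sub-threshold sample and the crossing sample; without, it is the
    crossing sample's time.  Both are reported relative to the onset.
    """
    if onset is None:
        if trial is None or not trial.onsets:
            raise ValueError("need an onset (directly or via trial)")
        onset = trial.onsets[0]
    if response_window is None:
        response_window = trial.response_window if trial is not None else 2_000.0
    idx = _window_indices(dff.times, onset, response_window)
    if len(idx) == 0:
        return None
    v = dff.valid[idx]
    d = dff.dff[idx]
    start = _first_qualifying_run(d >= threshold, v, min_consecutive)
    if start is None:
        return None
    i = idx[start]                      # global index of crossing sample
    t_cross = dff.times[i]
    if interpolate and i > 0 and dff.valid[i - 1] and dff.dff[i - 1] < threshold:
        t0, t1 = dff.times[i - 1], dff.times[i]
        d0, d1 = dff.dff[i - 1], dff.dff[i]
        t_cross = t0 + (threshold - d0) * (t1 - t0) / (d1 - d0)
    return float(t_cross - onset)


def fold_change(
    values: np.ndarray,
    times: np.ndarray,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    valid: np.ndarray | None = None,
) -> float:
    """Post/pre ratio of mean signal, e.g. terminal activation fold change."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    ok = np.ones(values.shape, bool) if valid is None else np.asarray(valid, bool)
    pre = ok & (times >= pre_window[0]) & (times < pre_window[1])
    post = ok & (times >= post_window[0]) & (times < post_window[1])
    if not pre.any() or not post.any():
        raise ValueError("both windows must contain valid samples")
    pre_mean = float(values[pre].mean())
    if pre_mean <= 0:
        raise ValueError("pre-window mean must be positive")
    return float(values[post].mean()) / pre_mean


def responder_fraction(calls: pd.DataFrame) -> dict[str, PopulationStats]:
    """Responder fractions per population: per-field fraction, then mean +/- SEM.

    ``calls`` has one row per (population, field, roi_id, trial) with a
    boolean ``responsive`` column; an ROI is counted responsive when it
    responds in at least half of its trials (majority rule).  An optional
    ``latency_ms`` column contributes the latency list (per-ROI median over
    its responsive trials).
    """
    required = {"population", "field", "roi_id", "responsive"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls must have columns {sorted(required)}")
    if len(calls) == 0:
        raise ValueError("empty population")
    out: dict[str, PopulationStats] = {}
    for pop, sub in calls.groupby("population", sort=True):
        roi_resp = (
            sub.groupby(["field", "roi_id"])["responsive"].mean() >= 0.5
        )
        fracs = roi_resp.groupby("field").mean()
        field_fractions = fracs.tolist()
        grand = float(np.mean(field_fractions))
        sem = float(np.std(field_fractions, ddof=1) / np.sqrt(len(field_fractions))) \
            if len(field_fractions) > 1 else 0.0
        latencies: list[float] = []
        if "latency_ms" in sub.columns:
            resp_rows = sub[sub["responsive"] & sub["latency_ms"].notna()]
            lat = resp_rows.groupby(["field", "roi_id"])["latency_ms"].median()
            latencies = [float(x) for _, x in lat.items() if roi_resp.get(_, False)]
        out[str(pop)] = PopulationStats(
            label=str(pop),
            n_rois=int(roi_resp.size),
            n_responsive=int(roi_resp.sum()),
            field_fractions=field_fractions,
            responder_fraction=grand,
            sem=sem,
            latencies=latencies,
            mean_latency=float(np.mean(latencies)) if latencies else None,
        )
    return out


def latency_modes(
    latencies: np.ndarray | list[float],
    bandwidth: float = DEFAULT_KDE_BANDWIDTH_MS,
    peak_rel_floor: float = DEFAULT_PEAK_REL_FLOOR,
) -> ModeEstimate:
    """Modes of a latency sample from a Gaussian KDE on a 1-ms grid.

    The density is evaluated on ``[0, max(latency) + 3 * bandwidth]`` at
    1 ms spacing with kernel standard deviation ``bandwidth`` (ms).  Modes
    are strict local maxima whose density is at least ``peak_rel_floor``
    times the global maximum, returned in ascending order.
    """
    x = np.asarray(latencies, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 latencies for mode estimation")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.arange(0.0, float(x.max()) + 3.0 * bandwidth + 1.0, 1.0)
    z = (grid[:, None] - x[None, :]) / bandwidth
    density = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * bandwidth * np.sqrt(2 * np.pi))
    interior = np.flatnonzero(
        (density[1:-1] > density[:-2]) & (density[1:-1] > density[2:])
    ) + 1
    floor = peak_rel_floor * density.max()
    keep = interior[density[interior] >= floor]
    return ModeEstimate(
        modes=[float(grid[i]) for i in keep],
        bandwidth=float(bandwidth),
        density_at_modes=[float(density[i]) for i in keep],
        grid=grid,
        density=density,
    )


def ks_two_sample(a: np.ndarray | list[float], b: np.ndarray | list[float]) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum of |ECDF_a - ECDF_b| over all step points; the
    p-value comes from the asymptotic Kolmogorov distribution at
    ``sqrt(n_a n_b / (n_a + n_b)) * D``.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pts = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pts, side="right") / a.size
    cdf_b = np.searchsorted(b, pts, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = a.size * b.size / (a.size + b.size)
    p = float(kolmogorov(np.sqrt(en) * d))
    return KsResult(statistic=d, pvalue=min(1.0, max(0.0, p)), n_a=int(a.size), n_b=int(b.size))


def compare_latency_populations(
    a: np.ndarray | list[float],
    b: np.ndarray | list[float],
) -> dict:
    """Compare a faster population ``a`` against ``b`` on mean latency.

    Percent reduction = 100 * (mean_b - mean_a) / mean_b, plus the K-S
    comparison of the two latency distributions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    mean_a = float(a.mean())
    mean_b = float(b.mean())
    if mean_b <= 0:
        raise ValueError("mean of reference population must be positive")
    return {
        "mean_a": mean_a,
        "mean_b": mean_b,
        "percent_reduction": 100.0 * (mean_b - mean_a) / mean_b,
        "ks": ks_two_sample(a, b),
    }
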