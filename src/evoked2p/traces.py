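"""ROI fluorescence traces and per-trial dF/F normalization.

The raw readout of each cell is the mean fluorescence over its ROI's valid
pixels, one sample per frame (frame-scan, 33.3 ms default) or per line
(line-scan, declared sample period, 1 ms default).  Activity is expressed
as dF/F aligned to an individual trial baseline F0, the mean signal over
the 10 s preceding that trial's stimulus onset.  The baseline window is
half-open, [onset - baseline, onset): the onset instant never contaminates
F0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .movie import Movie
from .rois import RoiSet

DEFAULT_BASELINE_MS = 10_000.0
DEFAULT_RESPONSE_WINDOW_FRAME_MS = 2_000.0
DEFAULT_RESPONSE_WINDOW_LINE_MS = 500.0
DEFAULT_LINE_SAMPLE_PERIOD_MS = 1.0


@dataclass
class TraceMatrix:
    """ROI x time fluorescence with a shared, uniform time base (ms)."""

    values: np.ndarray          # (n_rois, n_samples)
    times: np.ndarray           # (n_samples,) ms, strictly increasing, uniform
    roi_ids: list[str]
    valid: np.ndarray | None = None   # bool, same shape as values
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        self.roi_ids = [str(r) for r in self.roi_ids]
        if self.values.shape != (len(self.roi_ids), len(self.times)):
            raise ValueError("values must be (n_rois, n_samples)")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time base must be strictly increasing and uniform")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask shape must match values")

    @property
    def sample_period(self) -> float:
        if len(self.times) < 2:
            raise ValueError("need >= 2 samples for a sample period")
        return float(self.times[1] - self.times[0])

    def row(self, roi_id: str) -> int:
        return self.roi_ids.index(str(roi_id))

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, rid in enumerate(self.roi_ids):
            rows.append(pd.DataFrame({
                "roi_id": rid,
                "t_ms": self.times,
                "F": self.values[i],
                "valid": self.valid[i],
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, labels: dict[str, str] | None = None) -> "TraceMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        roi_ids = list(dict.fromkeys(df["roi_id"].astype(str)))
        times = np.sort(df.loc[df["roi_id"].astype(str) == roi_ids[0], "t_ms"].to_numpy())
        values = np.empty((len(roi_ids), len(times)))
        valid = np.ones(values.shape, dtype=bool)
        for i, rid in enumerate(roi_ids):
            sub = df[df["roi_id"].astype(str) == rid].sort_values("t_ms")
            values[i] = sub["F"].to_numpy()
            if "valid" in sub:
                valid[i] = sub["valid"].to_numpy(bool)
        return cls(values=values, times=times, roi_ids=roi_ids,
                   valid=valid, labels=labels or {})


@dataclass
class TrialSpec:
    """Stimulus schedule: onsets, baseline length and response window (ms)."""

    onsets: list[float]
    baseline_duration: float = DEFAULT_BASELINE_MS
    response_window: float = DEFAULT_RESPONSE_WINDOW_FRAME_MS
    stimulus: str = ""
    trial_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.onsets = [float(t) for t in self.onsets]
        if sorted(self.onsets) != self.onsets:
            raise ValueError("onsets must be sorted")
        if self.baseline_duration <= 0 or self.response_window <= 0:
            raise ValueError("baseline_duration and response_window must be positive")
        if self.trial_ids is None:
            self.trial_ids = [f"trial{i}" for i in range(len(self.onsets))]

    @classmethod
    def from_csv(cls, path: str | Path, baseline_duration: float = DEFAULT_BASELINE_MS,
                 response_window: float = DEFAULT_RESPONSE_WINDOW_FRAME_MS) -> "TrialSpec":
        df = pd.read_csv(path).sort_values("onset_ms")
        return cls(
            onsets=df["onset_ms"].tolist(),
            baseline_duration=baseline_duration,
            response_window=response_window,
            stimulus=str(df["stimulus"].iloc[0]) if "stimulus" in df else "",
            trial_ids=[str(t) for t in df["trial_id"]] if "trial_id" in df else None,
        )


@dataclass
class DffTrace:
    """Per-trial dF/F trace for one ROI: dff(t) = (F(t) - F0) / F0."""

    dff: np.ndarray
    times: np.ndarray
    f0: float
    roi_id: str = ""
    trial_id: str = ""
    valid: np.ndarray | None = None
    baseline_truncated: bool = False

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.dff.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)


def extract_traces(movie: Movie, rois: RoiSet) -> TraceMatrix:
    """Mean fluorescence of each ROI's valid pixels, one sample per frame.

    A sample is masked when every pixel of the ROI is invalid in that frame
    (e.g. the ROI fell entirely on a registration-exposed border).
    """
    h, w = movie.shape
    n = movie.n_frames
    values = np.empty((len(rois.roi_ids), n))
    valid = np.ones((len(rois.roi_ids), n), dtype=bool)
    mask = movie.valid_mask()
    for i, rid in enumerate(rois.roi_ids):
        pts = rois.pixels[rid]
        if np.any(pts[:, 0] >= h) or np.any(pts[:, 1] >= w) or np.any(pts < 0):
            raise ValueError(f"ROI {rid!r} outside the {h}x{w} grid")
        px = movie.frames[:, pts[:, 0], pts[:, 1]]          # (n_frames, n_px)
        ok = mask[:, pts[:, 0], pts[:, 1]]
        cnt = ok.sum(axis=1)
        with np.errstate(invalid="ignore"):
            values[i] = np.where(cnt > 0, (px * ok).sum(axis=1) / np.maximum(cnt, 1), 0.0)
        valid[i] = cnt > 0
    return TraceMatrix(values=values, times=movie.times, roi_ids=rois.roi_ids,
                       valid=valid, labels=dict(rois.labels))


def trial_baseline(
    values: np.ndarray,
    times: np.ndarray,
    onset: float,
    baseline_duration: float = DEFAULT_BASELINE_MS,
    valid: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Trial baseline F0: mean signal over [onset - baseline_duration, onset).

    Returns ``(F0, truncated)``; ``truncated`` is set when the recording
    covers less than the full baseline before the onset (the mean is then
    taken over what exists).  Raises if no valid pre-onset sample exists or
    if F0 <= 0 (broken input).
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    ok = np.ones(values.shape, bool) if valid is None else np.asarray(valid, bool)
    win = (times >= onset - baseline_duration) & (times < onset) & ok
    if not win.any():
        raise ValueError(f"no valid samples in the {baseline_duration} ms window before onset {onset}")
    f0 = float(values[win].mean())
    if f0 <= 0:
        raise ValueError(f"non-positive baseline F0={f0}; input is broken")
    truncated = times[0] > onset - baseline_duration
    return f0, bool(truncated)


def compute_dff(
    values: np.ndarray,
    f0: float,
    times: np.ndarray | None = None,
    valid: np.ndarray | None = None,
    roi_id: str = "",
    trial_id: str = "",
    baseline_truncated: bool = False,
) -> DffTrace:
    """dF/F relative to a trial baseline: (F - F0) / F0, masks propagated."""
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    return DffTrace(dff=(values - f0) / f0, times=times, f0=float(f0),
                    roi_id=roi_id, trial_id=trial_id, valid=valid,
                    baseline_truncated=baseline_truncated)


def per_trial_dff(traces: TraceMatrix, trials: TrialSpec) -> list[DffTrace]:
    """Baseline-normalize every ROI for every trial of a schedule."""
    out: list[DffTrace] = []
    for i, rid in enumerate(traces.roi_ids):
        for onset, tid in zip(trials.onsets, trials.trial_ids):
            f0, trunc = trial_baseline(traces.values[i], traces.times, onset,
                                       trials.baseline_duration, valid=traces.valid[i])
            out.append(compute_dff(traces.values[i], f0, times=traces.times,
                                   valid=traces.valid[i], roi_id=rid, trial_id=tid,
                                   baseline_truncated=trunc))
    return out


def dff_to_frame(dffs: list[DffTrace]) -> pd.DataFrame:
    rows = []
    for d in dffs:
        rows.append(pd.DataFrame({
            "roi_id": d.roi_id, "trial_id": d.trial_id,
            "t_ms": d.times, "dff": d.dff, "valid": d.valid,
        }))
    return pd.concat(rows, ignore_index=True)
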