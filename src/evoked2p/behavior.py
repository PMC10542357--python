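"""Deterministic scoring rules for nociceptive behavioral assays.

von Frey: filaments applied five times each in ascending force order; the
mechanical threshold is the lowest force evoking withdrawal on at least
three of the five applications.  Escape from foot shock is timed from the
first escape frame of a 30 frames/s video.  Thermal and motor latencies
are clamped at protective cutoffs (Hargreaves 20 s, hot plate 30 s, beam
60 s) with explicit censoring so downstream means stay reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

DEFAULT_N_TRIALS = 5
DEFAULT_CRITERION = 3
DEFAULT_FPS = 30.0

ASSAY_CUTOFFS_S: dict[str, float] = {
    "hargreaves": 20.0,
    "hot_plate": 30.0,
    "beam": 60.0,
}


@dataclass
class VonFreyRecord:
    """Responses per filament, forces strictly ascending (grams)."""

    forces_g: list[float]
    responses: list[int]
    n_trials: int = DEFAULT_N_TRIALS
    animal: str = ""

    def __post_init__(self) -> None:
        if len(self.forces_g) == 0:
            raise ValueError("empty von Frey record")
        if len(self.forces_g) != len(self.responses):
            raise ValueError("forces and responses must align")
        f = np.asarray(self.forces_g, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("forces must be strictly increasing")
        for r in self.responses:
            if not (0 <= r <= self.n_trials):
                raise ValueError(f"response count {r} outside [0, {self.n_trials}]")


@dataclass
class EscapeRecord:
    """First escape frame of a foot-shock trial video."""

    first_escape_frame: int | None
    fps: float = DEFAULT_FPS
    trial_length_s: float | None = None
    animal: str = ""
    trial: str = ""

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.first_escape_frame is not None and self.first_escape_frame < 0:
            raise ValueError("first_escape_frame must be >= 0")


@dataclass
class LatencyMeasure:
    """Latency clamped at a protective cutoff, censoring made explicit."""

    latency_s: float
    cutoff_s: float
    censored: bool


def von_frey_threshold(
    record: VonFreyRecord,
    criterion: int = DEFAULT_CRITERION,
) -> tuple[float, bool]:
    """Mechanical threshold: lowest force with >= ``criterion`` responses.

    Returns ``(force_g, censored)``; when no filament reaches the
    criterion, the highest force is returned with ``censored=True``.
    """
    if criterion > record.n_trials:
        raise ValueError("criterion cannot exceed n_trials")
    for force, resp in zip(record.forces_g, record.responses):
        if resp >= criterion:
            return float(force), False
    return float(record.forces_g[-1]), True


def escape_latency(record: EscapeRecord) -> tuple[float, bool]:
    """Escape latency in seconds from the first escape frame.

    Exact rational arithmetic (frame / fps) so e.g. frame 15 at 30 fps is
    exactly 0.5 s.  If no escape occurred, the latency is censored at the
    trial length.
    """
    if record.first_escape_frame is None:
        if record.trial_length_s is None:
            raise ValueError("no escape frame and no trial length to censor at")
        return float(record.trial_length_s), True
    lat = Fraction(record.first_escape_frame) / Fraction(record.fps).limit_denominator(10**6)
    return float(lat), False


def apply_cutoff(raw_latency_s: float, assay: str) -> LatencyMeasure:
    """Clamp a raw latency at the assay's protective cutoff."""
    if raw_latency_s < 0:
        raise ValueError("latency must be >= 0")
    key = assay.strip().lower().replace(" ", "_").replace("-", "_")
    if key not in ASSAY_CUTOFFS_S:
        raise ValueError(f"unknown assay {assay!r}; known: {sorted(ASSAY_CUTOFFS_S)}")
    cutoff = ASSAY_CUTOFFS_S[key]
    censored = raw_latency_s >= cutoff
    return LatencyMeasure(latency_s=min(raw_latency_s, cutoff), cutoff_s=cutoff,
                          censored=censored)


def score_von_frey_table(df: pd.DataFrame, criterion: int = DEFAULT_CRITERION) -> pd.DataFrame:
    """Score a long-format table (animal, force_g, responses) per animal."""
    rows = []
    for animal, sub in df.groupby("animal", sort=True):
        sub = sub.sort_values("force_g")
        rec = VonFreyRecord(forces_g=sub["force_g"].tolist(),
                            responses=sub["responses"].tolist(), animal=str(animal))
        thr, cens = von_frey_threshold(rec, criterion=criterion)
        rows.append({"animal": animal, "threshold_g": thr, "censored": cens})
    return pd.DataFrame(rows)


def score_escape_table(df: pd.DataFrame, fps: float = DEFAULT_FPS) -> pd.DataFrame:
    """Score a table (animal, trial, first_escape_frame) of escape videos."""
    rows = []
    for _, r in df.iterrows():
        rec = EscapeRecord(first_escape_frame=int(r["first_escape_frame"]), fps=fps,
                           animal=str(r["animal"]), trial=str(r.get("trial", "")))
        lat, cens = escape_latency(rec)
        rows.append({"animal": r["animal"], "trial": r.get("trial", ""),
                     "latency_s": lat, "censored": cens})
    return pd.DataFrame(rows)


def score_latency_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply assay cutoffs to a table (animal, assay, raw_s)."""
    rows = []
    for _, r in df.iterrows():
        m = apply_cutoff(float(r["raw_s"]), str(r["assay"]))
        rows.append({"animal": r["animal"], "assay": r["assay"],
                     "latency_s": m.latency_s, "cutoff_s": m.cutoff_s,
                     "censored": m.censored})
    return pd.DataFrame(rows)
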