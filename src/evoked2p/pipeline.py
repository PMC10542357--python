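"""End-to-end orchestration: register -> extract -> evoked statistics.

A single validated :class:`RunConfig` drives the stages; every stage
persists its intermediate artifact (registered TIFF, shift CSV, trace CSV,
dF/F CSV, call CSV) so each step is independently auditable, and the final
JSON report embeds the config hash, seed and package version so identical
configs reproduce identical reports bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .evoked import (
    DEFAULT_KDE_BANDWIDTH_MS,
    DEFAULT_MIN_CONSECUTIVE_FRAME,
    DEFAULT_PEAK_REL_FLOOR,
    DEFAULT_THRESHOLD,
    compare_latency_populations,
    detect_response,
    latency_modes,
    responder_fraction,
)
from .movie import Movie, read_movie, write_movie
from .registration import DEFAULT_MAX_SHIFT, DEFAULT_SCORE_FLOOR, DEFAULT_STABILITY_QUANTILE, register_movie
from .rois import RoiSet
from .traces import DEFAULT_BASELINE_MS, TrialSpec, extract_traces, per_trial_dff, dff_to_frame

logger = logging.getLogger("evoked2p.pipeline")


class RunConfig(BaseModel):
    """Validated pipeline configuration (JSON/YAML-serializable schema)."""

    # stage toggles
    do_register: bool = True
    do_extract: bool = True
    do_evoked: bool = True
    # inputs
    movie_path: str | None = None
    rois_path: str | None = None
    trials_path: str | None = None
    out_dir: str = "pipeline_out"
    # parameters
    frame_period_ms: float = Field(33.3, gt=0)
    max_shift: int = Field(DEFAULT_MAX_SHIFT, ge=0)
    stability_quantile: float = Field(DEFAULT_STABILITY_QUANTILE, gt=0, le=1)
    score_floor: float = DEFAULT_SCORE_FLOOR
    threshold: float = Field(DEFAULT_THRESHOLD, gt=0)
    baseline_ms: float = Field(DEFAULT_BASELINE_MS, gt=0)
    response_window_ms: float = Field(2_000.0, gt=0)
    min_consecutive: int = Field(DEFAULT_MIN_CONSECUTIVE_FRAME, ge=1)
    kde_bandwidth_ms: float = Field(DEFAULT_KDE_BANDWIDTH_MS, gt=0)
    peak_rel_floor: float = Field(DEFAULT_PEAK_REL_FLOOR, ge=0, le=1)
    field_id: str = "fov0"
    seed: int = 0

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(
    config: RunConfig,
    movie: Movie | None = None,
    rois: RoiSet | None = None,
    trials: TrialSpec | None = None,
) -> dict:
    """Execute the configured stages and return the report dict.

    Inputs may be passed in memory or read from the configured paths.
    Failures abort with a stage-tagged error message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log")
    logger.addHandler(fh)
    try:
        return _run(config, movie, rois, trials, out)
    finally:
        logger.removeHandler(fh)
        fh.close()


def _run(config: RunConfig, movie, rois, trials, out: Path) -> dict:
    if movie is None:
        if config.movie_path is None:
            raise RuntimeError("[input] no movie provided")
        movie = read_movie(config.movie_path, frame_period=config.frame_period_ms)
    if rois is None:
        if config.rois_path is None:
            raise RuntimeError("[input] no ROI set provided")
        p = Path(config.rois_path)
        rois = (RoiSet.from_polygon_json(p, movie.shape) if p.suffix == ".json"
                else RoiSet.from_label_tiff(p))
    if trials is None:
        if config.trials_path is None:
            raise RuntimeError("[input] no trial table provided")
        trials = TrialSpec.from_csv(config.trials_path,
                                    baseline_duration=config.baseline_ms,
                                    response_window=config.response_window_ms)

    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }

    if config.do_register:
        logger.info("register: max_shift=%d stability_quantile=%.2f",
                    config.max_shift, config.stability_quantile)
        try:
            movie, shifts = register_movie(movie, max_shift=config.max_shift,
                                           stability_quantile=config.stability_quantile,
                                           score_floor=config.score_floor)
        except Exception as e:  # pragma: no cover - defensive
            raise RuntimeError(f"[register] {e}") from e
        write_movie(movie, out / "registered.tif")
        shifts.to_csv(out / "shifts.csv")
        report["stages"].append("register")
        report["n_low_confidence_frames"] = int(shifts.low_confidence.sum())

    if config.do_extract:
        logger.info("extract: %d ROIs", len(rois.roi_ids))
        try:
            traces = extract_traces(movie, rois)
            dffs = per_trial_dff(traces, trials)
        except Exception as e:
            raise RuntimeError(f"[extract] {e}") from e
        traces.to_csv(out / "traces.csv")
        dff_to_frame(dffs).to_csv(out / "dff.csv", index=False, float_format="%.17g")
        report["stages"].append("extract")
    else:
        dffs = None

    if config.do_evoked:
        if dffs is None:
            raise RuntimeError("[evoked] extract stage required before evoked")
        logger.info("evoked: threshold=%.2f window=%.0f ms", config.threshold,
                    config.response_window_ms)
        try:
            rows = []
            for d in dffs:
                onset = trials.onsets[trials.trial_ids.index(d.trial_id)]
                call = detect_response(d, onset=onset,
                                       response_window=config.response_window_ms,
                                       threshold=config.threshold,
                                       min_consecutive=config.min_consecutive)
                rows.append({
                    "population": rois.label_of(d.roi_id),
                    "field": config.field_id,
                    "roi_id": d.roi_id,
                    "trial_id": d.trial_id,
                    "responsive": call.responsive,
                    "latency_ms": call.latency_ms,
                    "peak_dff": call.peak_dff,
                })
            calls = pd.DataFrame(rows)
            calls.to_csv(out / "calls.csv", index=False, float_format="%.17g")
            stats = responder_fraction(calls)
        except Exception as e:
            raise RuntimeError(f"[evoked] {e}") from e
        report["stages"].append("evoked")
        pops = {}
        for label, st in stats.items():
            entry = {
                "n_rois": st.n_rois,
                "n_responsive": st.n_responsive,
                "responder_fraction": st.responder_fraction,
                "sem": st.sem,
                "mean_latency_ms": st.mean_latency,
                "latencies_ms": st.latencies,
            }
            if len(st.latencies) >= 5:
                m = latency_modes(st.latencies, bandwidth=config.kde_bandwidth_ms,
                                  peak_rel_floor=config.peak_rel_floor)
                entry["latency_modes_ms"] = m.modes
            pops[label] = entry
        report["populations"] = pops
        labels = sorted(pops)
        if len(labels) == 2:
            la, lb = labels
            a = stats[la].latencies
            b = stats[lb].latencies
            if a and b:
                if float(np.mean(a)) > float(np.mean(b)):
                    la, lb, a, b = lb, la, b, a
                cmpres = compare_latency_populations(a, b)
                report["latency_comparison"] = {
                    "faster_population": la,
                    "slower_population": lb,
                    "mean_faster_ms": cmpres["mean_a"],
                    "mean_slower_ms": cmpres["mean_b"],
                    "percent_reduction": cmpres["percent_reduction"],
                    "ks_statistic": cmpres["ks"].statistic,
                    "ks_pvalue": cmpres["ks"].pvalue,
                }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
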