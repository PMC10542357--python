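"""Seeded generators with machine-readable ground truth.

Everything downstream is validated against data whose truth is known:
GCaMP6s-like stimulus-locked transients (saturating rise, slow exponential
decay), population latency structure (bimodal 40/70 ms for layer 5 versus
unimodal 70 ms for layer 4), responder fractions controlled by an
amplitude distribution interacting with the 10% detection threshold,
rigid x-y jitter, additive Gaussian noise, and behavioral response tables
from logistic force-response curves.  Identical config + seed always
reproduces identical output, and a :class:`SimTruth` record accompanies
every dataset.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .behavior import EscapeRecord, VonFreyRecord
from .movie import Movie, translate_frame
from .rois import RoiSet
from .traces import TraceMatrix

DEFAULT_TAU_R_MS = 20.0      # GCaMP6s-like rise
DEFAULT_TAU_D_MS = 1_500.0   # GCaMP6s-like decay
DEFAULT_NOISE_SIGMA_FRAC = 0.02
DEFAULT_F0 = 100.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------- transients

@dataclass
class TransientParams:
    """Kinetic surrogate for a calcium transient.

    ``amplitude`` is the peak dF/F of the rendered transient; ``tau_r`` and
    ``tau_d`` are the rise and decay time constants in ms (``tau_d=None``
    means no decay); ``onset`` is the transient onset in ms post-stimulus.
    """

    amplitude: float
    tau_r: float = DEFAULT_TAU_R_MS
    tau_d: float | None = DEFAULT_TAU_D_MS
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.tau_r <= 0:
            raise ValueError("tau_r must be positive")
        if self.tau_d is not None and self.tau_d <= 0:
            raise ValueError("tau_d must be positive or None (no decay)")


def transient_kernel(t: np.ndarray | float, p: TransientParams) -> np.ndarray | float:
    """Raw kernel: 0 before onset, A*(1-exp(-dt/tau_r))*exp(-dt/tau_d) after.

    With ``tau_d=None`` the decay factor is 1 and the kernel saturates at
    the amplitude.  With a finite decay the raw kernel peaks below the
    amplitude; use :func:`kernel_peak_factor` to renormalize when the
    amplitude must equal the realized peak dF/F.
    """
    t = np.asarray(t, dtype=float)
    dt = t - p.onset
    rise = 1.0 - np.exp(-np.clip(dt, 0, None) / p.tau_r)
    decay = 1.0 if p.tau_d is None else np.exp(-np.clip(dt, 0, None) / p.tau_d)
    out = np.where(dt < 0, 0.0, p.amplitude * rise * decay)
    return out if out.ndim else float(out)


def kernel_peak_factor(tau_r: float, tau_d: float | None) -> float:
    """Peak of the unit-amplitude kernel: 1 for no decay, else the closed
    form at t* = tau_r * ln(1 + tau_d / tau_r)."""
    if tau_d is None:
        return 1.0
    t_star = tau_r * math.log(1.0 + tau_d / tau_r)
    return (1.0 - math.exp(-t_star / tau_r)) * math.exp(-t_star / tau_d)


def peak_normalized_transient(t: np.ndarray, p: TransientParams) -> np.ndarray:
    """Transient whose realized peak dF/F equals ``p.amplitude`` exactly."""
    scale = 1.0 / kernel_peak_factor(p.tau_r, p.tau_d)
    scaled = dataclasses.replace(p, amplitude=p.amplitude * scale)
    return transient_kernel(t, scaled)


# ------------------------------------------------------------- latency model

@dataclass
class LatencyMixture:
    """Mixture of (optionally zero-width) Gaussian latency components, ms."""

    locations: list[float]
    weights: list[float]
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if len(self.locations) != len(self.weights):
            raise ValueError("locations and weights must align")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be >= 0 and sum to 1")
        if sorted(self.locations) != list(self.locations):
            raise ValueError("locations must be sorted ascending")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def mean(self) -> float:
        return float(np.dot(self.locations, self.weights))


def simulate_latencies(mix: LatencyMixture, n: int, seed) -> np.ndarray:
    """i.i.d. draws from the mixture, Gaussian components truncated at 0."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    comps = rng.choice(len(mix.locations), size=n, p=mix.weights)
    out = np.asarray(mix.locations, dtype=float)[comps]
    if mix.sigma > 0:
        out = out + mix.sigma * rng.standard_normal(n)
        bad = out < 0
        while bad.any():  # truncate at 0 by redrawing
            k = int(bad.sum())
            out[bad] = np.asarray(mix.locations, float)[comps[bad]] \
                + mix.sigma * rng.standard_normal(k)
            bad = out < 0
    return out


# ------------------------------------------------------------- scene config

@dataclass
class SceneConfig:
    """Reproducible description of a synthetic session.

    Trace-level fields are always used; the spatial fields (``grid_shape``,
    ``centers``, ``radii``, ``motion_path``) only matter for
    :func:`simulate_movie`.
    """

    n_rois: int = 40
    f0: float = DEFAULT_F0
    sample_period_ms: float = 33.3
    duration_ms: float = 40_000.0
    onsets_ms: list[float] = field(default_factory=lambda: [11_000.0])
    # responder model: fixed flags, or amplitude distribution vs threshold
    responder_flags: list[bool] | None = None
    amplitudes: list[float] | float | None = None
    amplitude_exponential_mean: float | None = None
    detection_threshold: float = 0.10
    # kinetics and latency
    tau_r: float = DEFAULT_TAU_R_MS
    tau_d: float | None = DEFAULT_TAU_D_MS
    latency: LatencyMixture | float = 40.0
    # noise
    noise_sigma_frac: float = DEFAULT_NOISE_SIGMA_FRAC
    # spatial (movie only)
    grid_shape: tuple[int, int] = (512, 512)
    soma_radius_px: float = 4.0
    motion_path: list[tuple[int, int]] | None = None
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if self.f0 <= 0 or self.sample_period_ms <= 0 or self.duration_ms <= 0:
            raise ValueError("f0, sample_period_ms and duration_ms must be positive")
        if self.noise_sigma_frac < 0:
            raise ValueError("noise_sigma_frac must be >= 0")


@dataclass
class SimTruth:
    """Ground truth accompanying every generated dataset."""

    responder: list[bool]
    amplitude: list[float]          # peak dF/F per ROI
    onset_latency_ms: list[float]   # transient onset per ROI, post-stimulus
    detection_threshold: float
    noiseless: np.ndarray | None = None       # (n_rois, n_samples) noiseless F
    noiseless_dff: np.ndarray | None = None   # (n_rois, n_samples)
    shifts: list[tuple[int, int]] | None = None  # per-frame applied (dx, dy)
    blob_overlap_warning: bool = False
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "responder": list(map(bool, self.responder)),
            "amplitude": list(map(float, self.amplitude)),
            "onset_latency_ms": list(map(float, self.onset_latency_ms)),
            "detection_threshold": self.detection_threshold,
            "shifts": None if self.shifts is None else [list(map(int, s)) for s in self.shifts],
            "blob_overlap_warning": self.blob_overlap_warning,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _draw_roi_params(config: SceneConfig, rng: np.random.Generator):
    n = config.n_rois
    if config.amplitude_exponential_mean is not None:
        amps = rng.exponential(config.amplitude_exponential_mean, size=n)
    elif config.amplitudes is not None:
        amps = np.broadcast_to(np.asarray(config.amplitudes, float), (n,)).copy()
    else:
        amps = np.full(n, 1.0)
    if config.responder_flags is not None:
        flags = np.asarray(config.responder_flags, dtype=bool)
        if flags.shape != (n,):
            raise ValueError("responder_flags length must equal n_rois")
        amps = np.where(flags, amps, 0.0)
    # truth flag: would the noiseless peak clear the detection threshold
    flags = amps >= config.detection_threshold
    if isinstance(config.latency, LatencyMixture):
        onsets = simulate_latencies(config.latency, n, rng)
    else:
        onsets = np.full(n, float(config.latency))
    return amps, flags, onsets


def simulate_traces(config: SceneConfig, seed=None) -> tuple[TraceMatrix, SimTruth]:
    """Stimulus-locked fluorescence traces with ground truth.

    F(t) = F0 * (1 + transient(t)) + Gaussian noise of sigma
    ``noise_sigma_frac * F0``; one transient per trial onset, per ROI, with
    the ROI's peak dF/F amplitude and onset latency.  The noiseless signal
    and all per-ROI parameters are emitted in the truth record.
    """
    rng = _rng(config.seed if seed is None else seed)
    amps, flags, onsets = _draw_roi_params(config, rng)
    times = np.arange(0.0, config.duration_ms, config.sample_period_ms)
    n, t = config.n_rois, len(times)
    dff = np.zeros((n, t))
    for i in range(n):
        if amps[i] <= 0:
            continue
        p = TransientParams(amplitude=amps[i], tau_r=config.tau_r,
                            tau_d=config.tau_d, onset=0.0)
        for stim in config.onsets_ms:
            p_i = dataclasses.replace(p, onset=stim + onsets[i])
            dff[i] += peak_normalized_transient(times, p_i)
    noiseless = config.f0 * (1.0 + dff)
    noise = config.noise_sigma_frac * config.f0 * rng.standard_normal((n, t))
    values = np.clip(noiseless + noise, 0.0, None)
    traces = TraceMatrix(values=values, times=times,
                         roi_ids=[f"roi{i:03d}" for i in range(n)])
    truth = SimTruth(responder=flags.tolist(), amplitude=amps.tolist(),
                     onset_latency_ms=onsets.tolist(),
                     detection_threshold=config.detection_threshold,
                     noiseless=noiseless, noiseless_dff=dff, seed=config.seed)
    return traces, truth


def simulate_movie(config: SceneConfig, seed=None) -> tuple[Movie, RoiSet, SimTruth]:
    """Render somata as Gaussian blobs modulated by their traces, apply a
    rigid per-frame shift path, and add noise.

    ROI masks are the blob cores (pixels at or above half the blob peak).
    Borders exposed by the shift are left at the background level.  The
    truth record carries the applied shift path; registration should
    recover its negation.
    """
    rng = _rng(config.seed if seed is None else seed)
    h, w = config.grid_shape
    n = config.n_rois
    amps, flags, onsets = _draw_roi_params(config, rng)
    times = np.arange(0.0, config.duration_ms, config.sample_period_ms)
    n_frames = len(times)

    # soma centers on a jittered grid, kept away from borders
    margin = int(4 * config.soma_radius_px + 2)
    side = int(np.ceil(np.sqrt(n)))
    ys = np.linspace(margin, h - margin, side)
    xs = np.linspace(margin, w - margin, side)
    centers = [(ys[i // side], xs[i % side]) for i in range(n)]

    rr, cc = np.mgrid[0:h, 0:w]
    blobs = np.empty((n, h, w))
    roi_pixels = {}
    for i, (cy, cx) in enumerate(centers):
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        blobs[i] = np.exp(-d2 / (2.0 * config.soma_radius_px ** 2))
        roi_pixels[f"roi{i:03d}"] = np.argwhere(blobs[i] >= 0.5)
    overlap_warning = bool(np.any(blobs.sum(axis=0) > 1.5))

    dff = np.zeros((n, n_frames))
    for i in range(n):
        if amps[i] <= 0:
            continue
        for stim in config.onsets_ms:
            p = TransientParams(amplitude=amps[i], tau_r=config.tau_r,
                                tau_d=config.tau_d, onset=stim + onsets[i])
            dff[i] += peak_normalized_transient(times, p)

    shifts = config.motion_path or [(0, 0)] * n_frames
    if len(shifts) != n_frames:
        raise ValueError("motion_path length must equal the frame count")
    frames = np.empty((n_frames, h, w))
    sigma = config.noise_sigma_frac * config.f0
    for k in range(n_frames):
        scene = config.background + np.tensordot(
            config.f0 * (1.0 + dff[:, k]), blobs, axes=(0, 0))
        dx, dy = shifts[k]
        shifted, ok = translate_frame(scene, int(dx), int(dy))
        shifted[~ok] = config.background
        if sigma > 0:
            shifted = shifted + sigma * rng.standard_normal((h, w))
        frames[k] = np.clip(shifted, 0.0, None)

    movie = Movie(frames=frames, frame_period=config.sample_period_ms)
    rois = RoiSet(pixels=roi_pixels, grid_shape=(h, w))
    # truth noiseless ROI-mean traces (unshifted scene) for recovery checks
    noiseless_roi = np.empty((n, n_frames))
    for i, rid in enumerate(rois.roi_ids):
        pts = rois.pixels[rid]
        weights = np.tensordot(blobs[:, pts[:, 0], pts[:, 1]], np.ones(len(pts)) / len(pts),
                               axes=(1, 0))  # mean blob weight of every soma on this ROI
        noiseless_roi[i] = config.background + (config.f0 * (1.0 + dff)).T @ weights
    truth = SimTruth(responder=flags.tolist(), amplitude=amps.tolist(),
                     onset_latency_ms=onsets.tolist(),
                     detection_threshold=config.detection_threshold,
                     noiseless=noiseless_roi, noiseless_dff=dff,
                     shifts=[(int(a), int(b)) for a, b in shifts],
                     blob_overlap_warning=overlap_warning, seed=config.seed)
    return movie, rois, truth


# ---------------------------------------------------------------- behavior

@dataclass
class BehaviorSimConfig:
    """Logistic von Frey responders and a stated escape-latency law."""

    n_animals: int = 10
    filament_forces_g: list[float] = field(
        default_factory=lambda: [0.16, 0.4, 0.6, 1.0, 1.4, 2.0])
    threshold_g: float = 0.8
    slope_per_g: float = math.inf     # inf = step response at threshold
    n_trials: int = 5
    escape_latency_mean_s: float = 0.5
    escape_latency_sd_s: float = 0.0
    n_escape_trials: int = 3
    fps: float = 30.0
    seed: int = 0


def simulate_behavior(config: BehaviorSimConfig, seed=None) -> tuple[list[VonFreyRecord], list[EscapeRecord]]:
    """Binomial(n_trials) filament responses from a logistic force-response
    curve, and escape frames from the stated latency distribution at fps."""
    rng = _rng(config.seed if seed is None else seed)
    vf: list[VonFreyRecord] = []
    esc: list[EscapeRecord] = []
    forces = np.asarray(config.filament_forces_g, dtype=float)
    for a in range(config.n_animals):
        if math.isinf(config.slope_per_g):
            p = (forces >= config.threshold_g).astype(float)
        else:
            p = 1.0 / (1.0 + np.exp(-config.slope_per_g * (forces - config.threshold_g)))
        responses = rng.binomial(config.n_trials, p)
        vf.append(VonFreyRecord(forces_g=forces.tolist(),
                                responses=[int(r) for r in responses],
                                n_trials=config.n_trials, animal=f"animal{a:03d}"))
        for trial in range(config.n_escape_trials):
            lat = config.escape_latency_mean_s
            if config.escape_latency_sd_s > 0:
                lat = max(0.0, lat + config.escape_latency_sd_s * rng.standard_normal())
            esc.append(EscapeRecord(first_escape_frame=int(round(lat * config.fps)),
                                    fps=config.fps, animal=f"animal{a:03d}",
                                    trial=f"trial{trial}"))
    return vf, esc
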