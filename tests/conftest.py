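import numpy as np
import pytest

from evoked2p import DffTrace, Movie, SceneConfig, simulate_movie


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_movie(rng):
    """Small movie with smooth random texture, no motion, no transients."""
    base = rng.random((48, 48))
    # smooth it so NCC has a well-defined single peak
    k = np.ones((5, 5)) / 25.0
    from scipy.signal import convolve2d

    base = convolve2d(base, k, mode="same", boundary="symm")
    frames = np.stack([base] * 6)
    return Movie(frames=frames, frame_period=33.3)


def make_dff(times, dff, **kw):
    return DffTrace(dff=np.asarray(dff, float), times=np.asarray(times, float), f0=100.0, **kw)


def jittered_scene(path, grid=(64, 64), n_rois=9, seed=3):
    """Zero-noise blob movie with a known integer shift path."""
    n_frames = len(path)
    cfg = SceneConfig(
        n_rois=n_rois, grid_shape=grid, sample_period_ms=33.3,
        duration_ms=33.3 * n_frames,  # arange end-exclusive: exactly n_frames samples
        onsets_ms=[], amplitudes=0.0, noise_sigma_frac=0.0,
        soma_radius_px=3.0, motion_path=list(path), seed=seed,
    )
    return simulate_movie(cfg)
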