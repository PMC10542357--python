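"""Rigid x-y motion correction by exhaustive normalized cross-correlation.

Awake head-fixed imaging drifts by a few pixels between the objective and
the cortex.  Each frame is realigned to a reference image (the average of
the stable frames) by the integer translation that maximizes the
zero-normalized cross-correlation (Pearson correlation over the overlap
region), searched exhaustively on ``[-max_shift, max_shift]^2``.  Ties are
broken toward the smallest displacement norm, then lexicographically, so
the estimator is fully deterministic.  Borders exposed by translation are
marked invalid rather than zero-filled, keeping downstream ROI averages
uncontaminated.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .movie import Movie, ReferenceImage, ShiftSeries, translate_frame

DEFAULT_MAX_SHIFT = 20
DEFAULT_SCORE_FLOOR = 0.3
DEFAULT_STABILITY_QUANTILE = 0.8


@lru_cache(maxsize=8)
def _candidate_shifts(max_shift: int) -> tuple[tuple[int, int], ...]:
    """All integer shifts in the search square, ordered by tie-break rule:
    smallest squared norm first, then lexicographic on (dx, dy)."""
    cands = [
        (dx, dy)
        for dx in range(-max_shift, max_shift + 1)
        for dy in range(-max_shift, max_shift + 1)
    ]
    cands.sort(key=lambda s: (s[0] * s[0] + s[1] * s[1], s[0], s[1]))
    return tuple(cands)


def _zncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None) -> float:
    """Pearson correlation of two equal-shape patches over ``mask``."""
    if mask is not None:
        a = a[mask]
        b = b[mask]
    else:
        a = a.ravel()
        b = b.ravel()
    if a.size < 2:
        return np.nan
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        return np.nan
    return float((a @ b) / denom)


def estimate_translation(
    frame: np.ndarray,
    reference: np.ndarray | ReferenceImage,
    max_shift: int = DEFAULT_MAX_SHIFT,
    frame_valid: np.ndarray | None = None,
    ref_valid: np.ndarray | None = None,
) -> tuple[int, int, float]:
    """Integer shift (dx, dy) of ``frame`` maximizing NCC with ``reference``.

    The returned shift is the correction to apply to the frame (see
    :func:`evoked2p.movie.translate_frame`).  The score is the peak
    zero-normalized cross-correlation, in [-1, 1].  A constant frame or
    reference makes the correlation undefined: (0, 0) is returned with a
    NaN score.
    """
    if isinstance(reference, ReferenceImage):
        reference = reference.image
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must share shape")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if np.ptp(frame) == 0.0 or np.ptp(reference) == 0.0:
        return 0, 0, np.nan

    h, w = frame.shape
    fv = np.ones((h, w), bool) if frame_valid is None else np.asarray(frame_valid, bool)
    rv = np.ones((h, w), bool) if ref_valid is None else np.asarray(ref_valid, bool)
    plain = fv.all() and rv.all()

    best_score = -np.inf
    best = (0, 0)
    for dx, dy in _candidate_shifts(max_shift):
        r0, r1 = max(0, dy), h + min(0, dy)
        c0, c1 = max(0, dx), w + min(0, dx)
        if r1 <= r0 or c1 <= c0:
            continue
        a = reference[r0:r1, c0:c1]
        b = frame[r0 - dy : r1 - dy, c0 - dx : c1 - dx]
        if plain:
            mask = None
        else:
            mask = rv[r0:r1, c0:c1] & fv[r0 - dy : r1 - dy, c0 - dx : c1 - dx]
            if mask.sum() < 2:
                continue
        score = _zncc(a, b, mask)
        if np.isnan(score):
            continue
        # strict > keeps the earliest candidate in tie-break order on ties
        if score > best_score:
            best_score = score
            best = (dx, dy)
    if not np.isfinite(best_score):
        return 0, 0, np.nan
    return best[0], best[1], best_score


def compute_reference(
    movie: Movie,
    stability_quantile: float = DEFAULT_STABILITY_QUANTILE,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> ReferenceImage:
    """Average image of the stable frames, used as registration target.

    Two-pass rule: pass 1 takes the all-frame mean as a provisional target
    and scores every frame by its peak NCC against it; pass 2 retains the
    frames whose score is at or above the ``1 - stability_quantile``
    quantile (i.e. the top ``stability_quantile`` fraction), applies each
    retained frame's estimated shift, and averages them pixel-wise over
    their valid support.  Pixels never covered by a retained frame fall
    back to the pass-1 mean.
    """
    if not (0.0 < stability_quantile <= 1.0):
        raise ValueError("stability_quantile must be in (0, 1]")
    frames = movie.frames
    if not np.all(np.isfinite(frames)):
        raise ValueError("movie contains non-finite pixels")
    n = movie.n_frames
    if n == 1:
        return ReferenceImage(image=frames[0].copy(), n_frames_used=1,
                              single_frame_warning=True)

    provisional = frames.mean(axis=0)
    shifts = []
    scores = np.empty(n)
    for k in range(n):
        dx, dy, s = estimate_translation(frames[k], provisional, max_shift)
        shifts.append((dx, dy))
        scores[k] = s
    # Anchor the reference in the first frame's coordinates: only relative
    # motion is identifiable against the (possibly offset) all-frame mean,
    # so subtract frame 0's estimate from every shift before averaging.
    dx0, dy0 = shifts[0]
    shifts = [(dx - dx0, dy - dy0) for dx, dy in shifts]

    if stability_quantile >= 1.0 or np.all(np.isnan(scores)):
        keep = np.ones(n, dtype=bool)
    else:
        thr = np.nanquantile(scores, 1.0 - stability_quantile)
        keep = scores >= thr  # NaN compares False: undefined frames dropped
        if not keep.any():
            keep = np.ones(n, dtype=bool)

    acc = np.zeros(movie.shape)
    cnt = np.zeros(movie.shape)
    src_valid = movie.valid_mask()
    for k in np.flatnonzero(keep):
        shifted, ok = translate_frame(frames[k], *shifts[k], valid=src_valid[k])
        acc[ok] += shifted[ok]
        cnt[ok] += 1
    image = provisional.copy()
    covered = cnt > 0
    image[covered] = acc[covered] / cnt[covered]
    return ReferenceImage(image=image, n_frames_used=int(keep.sum()))


def register_movie(
    movie: Movie,
    max_shift: int = DEFAULT_MAX_SHIFT,
    stability_quantile: float = DEFAULT_STABILITY_QUANTILE,
    score_floor: float = DEFAULT_SCORE_FLOOR,
    reference: ReferenceImage | None = None,
) -> tuple[Movie, ShiftSeries]:
    """Motion-correct every frame of ``movie`` against its stable-frame mean.

    Returns the registered movie (exposed border pixels invalid in its mask)
    and the per-frame :class:`ShiftSeries`.  Frames whose peak NCC falls
    below ``score_floor`` (or is undefined) are kept but flagged
    low-confidence.
    """
    if reference is None:
        reference = compute_reference(movie, stability_quantile, max_shift)
    n = movie.n_frames
    dxs = np.zeros(n, int)
    dys = np.zeros(n, int)
    scores = np.full(n, np.nan)
    src_valid = movie.valid_mask()
    out = np.empty_like(movie.frames)
    out_valid = np.empty(movie.frames.shape, dtype=bool)
    for k in range(n):
        dx, dy, s = estimate_translation(
            movie.frames[k], reference.image, max_shift,
            frame_valid=None if movie.valid is None else src_valid[k],
        )
        dxs[k], dys[k], scores[k] = dx, dy, s
        out[k], out_valid[k] = translate_frame(movie.frames[k], dx, dy,
                                               valid=src_valid[k])
    low = np.isnan(scores) | (scores < score_floor)
    shifts = ShiftSeries(dx=dxs, dy=dys, ncc_score=scores, low_confidence=low)
    registered = Movie(frames=out, frame_period=movie.frame_period,
                       origin_time=movie.origin_time, valid=out_valid)
    return registered, shifts
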