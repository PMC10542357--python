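"""Fluorescence movie container and rigid integer-pixel translation.

A :class:`Movie` is a frame-major stack of two-photon fluorescence images
with its acquisition clock (milliseconds per frame) attached.  Pixels may be
marked invalid — translation exposes borders, and downstream ROI averages
must never read exposed pixels — so validity travels with the data as a
boolean mask of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

DEFAULT_FRAME_PERIOD_MS = 33.3  # frame-scan acquisition clock


@dataclass
class Movie:
    """3-D fluorescence stack (frame, row, col) with acquisition metadata.

    Parameters
    ----------
    frames
        Intensities, shape ``(n_frames, height, width)``; finite and >= 0.
    frame_period
        Milliseconds per frame; must be positive.
    origin_time
        Session-clock time of the first frame in ms.
    valid
        Boolean mask, same shape as ``frames``; ``False`` marks pixels that
        must not enter ROI averages (e.g. borders exposed by registration).
        ``None`` means all pixels are valid.
    """

    frames: np.ndarray
    frame_period: float = DEFAULT_FRAME_PERIOD_MS
    origin_time: float = 0.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (frame, row, col), got ndim={self.frames.ndim}")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if np.any(self.frames < 0):
            raise ValueError("frames contain negative intensities")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.frames.shape:
                raise ValueError("valid mask shape must match frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Sample time of each frame in ms (frame-start convention)."""
        return self.origin_time + np.arange(self.n_frames) * self.frame_period

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.frames.shape, dtype=bool)
        return self.valid


@dataclass
class ReferenceImage:
    """Stable-frame average used as the registration target."""

    image: np.ndarray
    n_frames_used: int
    single_frame_warning: bool = False


@dataclass
class ShiftSeries:
    """Per-frame rigid correction (dx, dy) with its peak NCC score.

    ``dx`` moves the frame along columns (x), ``dy`` along rows (y); the
    stored shift is the correction *applied to* the frame.  ``ncc_score`` is
    NaN where the correlation was undefined (constant image).
    """

    dx: np.ndarray
    dy: np.ndarray
    ncc_score: np.ndarray
    low_confidence: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=int)
        self.dy = np.asarray(self.dy, dtype=int)
        self.ncc_score = np.asarray(self.ncc_score, dtype=float)
        if self.low_confidence is None:
            self.low_confidence = np.zeros(self.dx.shape, dtype=bool)
        else:
            self.low_confidence = np.asarray(self.low_confidence, dtype=bool)
        n = len(self.dx)
        if not (len(self.dy) == len(self.ncc_score) == len(self.low_confidence) == n):
            raise ValueError("ShiftSeries fields must have equal length")

    def __len__(self) -> int:
        return len(self.dx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "dx": self.dx,
                "dy": self.dy,
                "ncc_score": self.ncc_score,
                "low_confidence": self.low_confidence,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ShiftSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        low = df["low_confidence"].to_numpy(bool) if "low_confidence" in df else None
        return cls(
            dx=df["dx"].to_numpy(),
            dy=df["dy"].to_numpy(),
            ncc_score=df["ncc_score"].to_numpy(),
            low_confidence=low,
        )


def translate_frame(
    frame: np.ndarray,
    dx: int,
    dy: int,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Translate ``frame`` by ``(dx, dy)`` pixels (x = columns, y = rows).

    Output pixel ``(r, c)`` receives ``frame[r - dy, c - dx]``; border
    pixels with no source are set to 0 and marked invalid in the returned
    mask.  No interpolation — shifts are integer so intensities are never
    resampled.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    out = np.zeros_like(frame)
    out_valid = np.zeros((h, w), dtype=bool)
    src_valid = np.ones((h, w), dtype=bool) if valid is None else np.asarray(valid, bool)

    r0, r1 = max(0, dy), h + min(0, dy)
    c0, c1 = max(0, dx), w + min(0, dx)
    if r1 > r0 and c1 > c0:
        out[r0:r1, c0:c1] = frame[r0 - dy : r1 - dy, c0 - dx : c1 - dx]
        out_valid[r0:r1, c0:c1] = src_valid[r0 - dy : r1 - dy, c0 - dx : c1 - dx]
    out[~out_valid] = 0.0
    return out, out_valid


def read_movie(path: str | Path, frame_period: float = DEFAULT_FRAME_PERIOD_MS,
               origin_time: float = 0.0) -> Movie:
    """Read a multi-page TIFF stack as a :class:`Movie`."""
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    return Movie(frames=np.asarray(frames, dtype=float), frame_period=frame_period,
                 origin_time=origin_time)


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a :class:`Movie` to a multi-page float32 TIFF (frame-major)."""
    tifffile.imwrite(str(path), movie.frames.astype(np.float32))
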