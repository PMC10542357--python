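"""Regions of interest: cell-body masks on the imaging grid.

ROIs are sets of pixels, typically manually drawn around somata.  Two
ingestion routes are supported: a 16-bit label TIFF (pixel value = ROI id,
0 = background) and a polygon JSON file, rasterized by pixel-center
inclusion.  Each ROI may carry a population tag (e.g. ``layer5_SCRN`` vs
``layer4``) used by the population statistics downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from matplotlib.path import Path as MplPath


@dataclass
class RoiSet:
    """Mapping of ROI id -> pixel coordinates, with optional population tags.

    ``pixels[roi_id]`` is an ``(n, 2)`` integer array of (row, col) pairs.
    """

    pixels: dict[str, np.ndarray]
    labels: dict[str, str] = field(default_factory=dict)
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for roi_id, pts in self.pixels.items():
            pts = np.asarray(pts, dtype=int).reshape(-1, 2)
            if pts.shape[0] == 0:
                raise ValueError(f"ROI {roi_id!r} is empty")
            if self.grid_shape is not None:
                h, w = self.grid_shape
                inside = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
                if not inside.any():
                    raise ValueError(f"ROI {roi_id!r} lies fully outside the {h}x{w} grid")
                if not inside.all():
                    raise ValueError(f"ROI {roi_id!r} has pixels outside the grid")
            clean[str(roi_id)] = pts
        self.pixels = clean

    @property
    def roi_ids(self) -> list[str]:
        return list(self.pixels)

    def label_of(self, roi_id: str) -> str:
        return self.labels.get(roi_id, "default")

    @classmethod
    def from_label_image(
        cls,
        label_image: np.ndarray,
        labels: dict[str, str] | None = None,
    ) -> "RoiSet":
        """Build from a label image: pixel value k > 0 belongs to ROI ``str(k)``."""
        label_image = np.asarray(label_image)
        pixels = {}
        for k in np.unique(label_image):
            if k == 0:
                continue
            rc = np.argwhere(label_image == k)
            pixels[str(int(k))] = rc
        if not pixels:
            raise ValueError("label image contains no ROIs")
        return cls(pixels=pixels, labels=labels or {}, grid_shape=label_image.shape)

    @classmethod
    def from_label_tiff(cls, path: str | Path, labels: dict[str, str] | None = None) -> "RoiSet":
        return cls.from_label_image(tifffile.imread(str(path)), labels=labels)

    @classmethod
    def from_polygon_json(cls, path: str | Path, grid_shape: tuple[int, int]) -> "RoiSet":
        """Read polygons from JSON and rasterize by pixel-center inclusion.

        Schema: ``{"rois": [{"id": ..., "label": ..., "vertices": [[row, col], ...]}]}``.
        A pixel belongs to the ROI when its center (row + 0, col + 0 in array
        coordinates) falls inside the polygon.
        """
        spec = json.loads(Path(path).read_text())
        h, w = grid_shape
        rr, cc = np.mgrid[0:h, 0:w]
        centers = np.column_stack([rr.ravel(), cc.ravel()])
        pixels: dict[str, np.ndarray] = {}
        label_map: dict[str, str] = {}
        for roi in spec["rois"]:
            poly = MplPath(np.asarray(roi["vertices"], dtype=float))
            inside = poly.contains_points(centers)
            pts = centers[inside]
            if pts.shape[0] == 0:
                raise ValueError(f"polygon ROI {roi['id']!r} rasterizes to no pixels")
            rid = str(roi["id"])
            pixels[rid] = pts
            if "label" in roi:
                label_map[rid] = str(roi["label"])
        return cls(pixels=pixels, labels=label_map, grid_shape=grid_shape)

    def to_label_image(self, grid_shape: tuple[int, int] | None = None) -> np.ndarray:
        shape = grid_shape or self.grid_shape
        if shape is None:
            raise ValueError("grid_shape required")
        out = np.zeros(shape, dtype=np.uint16)
        for k, (roi_id, pts) in enumerate(self.pixels.items(), start=1):
            out[pts[:, 0], pts[:, 1]] = k
        return out
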