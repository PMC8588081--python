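"""Landmark-driven segmentation of the forehead and the two scleras.

Works from the standard 0-based 68-point facial landmark convention: points
17-26 are the eyebrows, 36-41 the right eye (viewer's left) and 42-47 the
left eye.  The forehead box spans the eyebrow columns and sits 20 px above
the highest eyebrow point with a fixed 120 px height; each sclera mask is the
filled convex hull of its six eye-contour points, which excludes eyelid skin
better than a bounding box would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon as _draw_polygon

__all__ = [
    "EYEBROW_RANGE",
    "RIGHT_EYE_RANGE",
    "LEFT_EYE_RANGE",
    "FOREHEAD_OFFSET",
    "FOREHEAD_HEIGHT",
    "LandmarkSet",
    "RegionMask",
    "DegenerateROIError",
    "forehead_roi",
    "sclera_roi",
    "segment_scene",
]

#: inclusive landmark index ranges, 0-based
EYEBROW_RANGE = (18, 25)
RIGHT_EYE_RANGE = (36, 41)
LEFT_EYE_RANGE = (42, 47)

#: forehead box: rows [y_min - OFFSET - HEIGHT, y_min - OFFSET) above the eyebrows
FOREHEAD_OFFSET = 20
FOREHEAD_HEIGHT = 120


class DegenerateROIError(ValueError):
    """Region of interest collapses to nothing (clipped away or degenerate hull)."""


@dataclass
class LandmarkSet:
    """68 (col, row) pixel landmarks plus the image dimensions they refer to."""

    points: np.ndarray
    image_shape: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=int)
        if self.points.shape != (68, 2):
            raise ValueError(f"expected 68 (col,row) points, got shape {self.points.shape}")
        h, w = self.image_shape
        cols, rows = self.points[:, 0], self.points[:, 1]
        if (cols < 0).any() or (cols >= w).any() or (rows < 0).any() or (rows >= h).any():
            raise ValueError("landmark points must lie inside the image bounds")

    def slice(self, index_range: tuple[int, int]) -> np.ndarray:
        lo, hi = index_range
        return self.points[lo : hi + 1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "image_shape": list(self.image_shape),
            "points": self.points.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        d = json.loads(Path(path).read_text())
        # scene sidecars store landmarks under "landmarks" with other metadata
        pts = d["points"] if "points" in d else d["landmarks"]
        shape = tuple(d.get("image_shape", (0, 0)))
        if shape == (0, 0):
            arr = np.asarray(pts)
            shape = (int(arr[:, 1].max()) + 1, int(arr[:, 0].max()) + 1)
        return cls(points=np.asarray(pts), image_shape=shape)


@dataclass
class RegionMask:
    """Boolean pixel mask for one region of interest."""

    mask: np.ndarray
    region_label: str  # forehead | left_sclera | right_sclera

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel_count == 0:
            raise DegenerateROIError(f"{self.region_label} mask is empty")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def forehead_roi(landmarks: LandmarkSet) -> RegionMask:
    """Axis-aligned forehead box above the eyebrow landmarks (points 18-25).

    Columns span [min, max] of the eyebrow columns (inclusive); rows span
    [y_min - 140, y_min - 20) where y_min is the smallest eyebrow row and
    "above" means decreasing row index.  The box is clipped to the image; a
    box fully clipped away raises :class:`DegenerateROIError`.
    """
    pts = landmarks.slice(EYEBROW_RANGE)
    h, w = landmarks.image_shape
    c0, c1 = int(pts[:, 0].min()), int(pts[:, 0].max())
    y_min = int(pts[:, 1].min())
    r0 = max(y_min - FOREHEAD_OFFSET - FOREHEAD_HEIGHT, 0)
    r1 = max(y_min - FOREHEAD_OFFSET, 0)
    r1 = min(r1, h)
    mask = np.zeros((h, w), dtype=bool)
    if r1 > r0:
        mask[r0:r1, c0 : c1 + 1] = True
    if not mask.any():
        raise DegenerateROIError("forehead box fully clipped away (face at image top)")
    return RegionMask(mask=mask, region_label="forehead")


def sclera_roi(landmarks: LandmarkSet, side: str) -> RegionMask:
    """Filled convex hull of the six eye-contour points for one sclera.

    ``side="left"`` uses points 42-47, ``side="right"`` points 36-41 (the
    subject's left/right eye respectively).
    """
    if side == "left":
        pts = landmarks.slice(LEFT_EYE_RANGE)
    elif side == "right":
        pts = landmarks.slice(RIGHT_EYE_RANGE)
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError as exc:
        raise DegenerateROIError(f"{side} eye points are degenerate (collinear?)") from exc
    verts = pts[hull.vertices]
    h, w = landmarks.image_shape
    rr, cc = _draw_polygon(verts[:, 1], verts[:, 0], shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        raise DegenerateROIError(f"{side} sclera hull rasterizes to an empty mask")
    return RegionMask(mask=mask, region_label=f"{side}_sclera")


def segment_scene(landmarks: LandmarkSet) -> dict[str, RegionMask]:
    """All three ROI masks keyed ``forehead`` / ``left_sclera`` / ``right_sclera``."""
    return {
        "forehead": forehead_roi(landmarks),
        "left_sclera": sclera_roi(landmarks, "left"),
        "right_sclera": sclera_roi(landmarks, "right"),
    }
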