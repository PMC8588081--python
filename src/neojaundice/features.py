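"""Multi-colorspace mean features from segmented regions.

Each region contributes 12 features: the per-channel means of its pixels in
RGB, full-range BT.601 YCbCr, CIELab (D65, sRGB) and HSV.  Conversions run on
real-valued pixels (no intermediate re-quantization) in the spaces' native
scales: RGB 0-255, YCbCr 0-255 with chroma centered at 128, L* 0-100 with
signed a*/b*, hue in degrees [0, 360) with S and V in [0, 1].

Hue is averaged arithmetically, like every other channel.  For the skin and
sclera tones this pipeline sees (hues well inside (0, 120) degrees) that is
unproblematic; for reds straddling the 0/360 wrap-around a circular mean
would differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor

from .segmentation import RegionMask

__all__ = [
    "COLOR_SPACES",
    "FeatureVector",
    "rgb_to_ycbcr_full",
    "roi_color_means",
    "feature_names",
    "assemble_features",
    "extract_scene_features",
]

#: feature-block order within each region
COLOR_SPACES = ("rgb", "ycbcr", "lab", "hsv")

# full-range BT.601 (JPEG) coefficients
_YCBCR_MATRIX = np.array([
    [0.299, 0.587, 0.114],
    [-0.168735892, -0.331264108, 0.5],
    [0.5, -0.418687589, -0.081312411],
])
_YCBCR_OFFSET = np.array([0.0, 128.0, 128.0])


def rgb_to_ycbcr_full(rgb: np.ndarray) -> np.ndarray:
    """Full-range BT.601 YCbCr from RGB in 0-255; returns floats in 0-255."""
    rgb = np.asarray(rgb, dtype=float)
    return rgb @ _YCBCR_MATRIX.T + _YCBCR_OFFSET


def roi_color_means(image: np.ndarray, mask: RegionMask | np.ndarray) -> np.ndarray:
    """The 12 per-channel means of the masked pixels across the four color spaces.

    Parameters
    ----------
    image : ndarray
        HxWx3, uint8 or float, on the 0-255 scale (calibrated).
    mask : RegionMask or bool ndarray
        Non-empty pixel mask.

    Returns
    -------
    ndarray of shape (12,)
        Means ordered rgb(3), ycbcr(3), lab(3), hsv(3).
    """
    m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, dtype=bool)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be HxWx3")
    if m.shape != image.shape[:2]:
        raise ValueError("mask shape does not match image")
    pixels = image[m].astype(float)
    if pixels.shape[0] == 0:
        raise ValueError("mask selects no pixels")

    rgb = pixels
    ycbcr = rgb_to_ycbcr_full(pixels)
    unit = pixels / 255.0
    lab = _skcolor.rgb2lab(unit.reshape(1, -1, 3)).reshape(-1, 3)
    hsv = _skcolor.rgb2hsv(unit.reshape(1, -1, 3)).reshape(-1, 3)
    hsv = hsv * np.array([360.0, 1.0, 1.0])

    return np.concatenate([
        rgb.mean(axis=0), ycbcr.mean(axis=0), lab.mean(axis=0), hsv.mean(axis=0)
    ])


def feature_names(roi: str) -> list[str]:
    """The 12 feature names for one region, ``<roi>_<space>_<channel 1..3>``."""
    return [f"{roi}_{space}_{ch}" for space in COLOR_SPACES for ch in (1, 2, 3)]


@dataclass
class FeatureVector:
    """Named color-mean features for one subject."""

    values: np.ndarray
    names: list[str]
    subject_id: str | None = None
    label: str | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names differ in length")
        if len(self.values) not in (12, 24, 36):
            raise ValueError(f"feature vector length must be 12/24/36, got {len(self.values)}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


FEATURE_SETS = ("skin", "eye", "fusion")


def assemble_features(
    skin12: np.ndarray | None,
    left12: np.ndarray | None,
    right12: np.ndarray | None,
    feature_set: str,
    subject_id: str | None = None,
    label: str | int | None = None,
) -> FeatureVector:
    """Assemble the requested condition's vector from per-region 12-blocks.

    ``skin`` -> the forehead block (12); ``eye`` -> left sclera followed by
    right sclera (24); ``fusion`` -> skin, left, right concatenated (36).
    """
    def _need(block, name):
        if block is None:
            raise ValueError(f"feature set {feature_set!r} requires the {name} block")
        block = np.asarray(block, dtype=float)
        if block.shape != (12,):
            raise ValueError(f"{name} block must have 12 values, got {block.shape}")
        return block

    if feature_set == "skin":
        values = _need(skin12, "skin")
        names = feature_names("skin")
    elif feature_set == "eye":
        values = np.concatenate([_need(left12, "left eye"), _need(right12, "right eye")])
        names = feature_names("left_eye") + feature_names("right_eye")
    elif feature_set == "fusion":
        values = np.concatenate([
            _need(skin12, "skin"), _need(left12, "left eye"), _need(right12, "right eye")
        ])
        names = feature_names("skin") + feature_names("left_eye") + feature_names("right_eye")
    else:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}, got {feature_set!r}")
    return FeatureVector(values=values, names=names, subject_id=subject_id, label=label)


def extract_scene_features(
    image: np.ndarray,
    masks: dict,
    feature_set: str = "fusion",
    subject_id: str | None = None,
    label: str | int | None = None,
) -> FeatureVector:
    """Region means -> assembled vector, given masks keyed forehead/left_sclera/right_sclera."""
    skin12 = roi_color_means(image, masks["forehead"]) if "forehead" in masks else None
    left12 = roi_color_means(image, masks["left_sclera"]) if "left_sclera" in masks else None
    right12 = roi_color_means(image, masks["right_sclera"]) if "right_sclera" in masks else None
    return assemble_features(skin12, left12, right12, feature_set,
                             subject_id=subject_id, label=label)
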