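"""Calibration-card white balancing.

The observed average color (R'w, G'w, B'w) of the card's white patch defines a
diagonal transform that maps it back to reference white:

    [R, G, B] = diag(255/R'w, 255/G'w, 255/B'w) . [R', G', B']

applied per pixel, then rounded half-up and clipped to [0, 255].  This removes
a per-channel multiplicative illumination cast; pixels already saturated at
255 are not recoverable and no inpainting is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import CardGeometry

__all__ = ["WhitePatchStats", "measure_white_patch", "apply_white_balance", "calibrate"]


class DegeneratePatchError(ValueError):
    """White patch unusable: empty region or a zero channel mean (would divide by zero)."""


@dataclass(frozen=True)
class WhitePatchStats:
    """Per-channel average of the white patch on the uncalibrated image."""

    mean_rgb: tuple[float, float, float]
    pixel_count: int

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise DegeneratePatchError("white patch contains no pixels")
        for m in self.mean_rgb:
            if not (0.0 < m <= 255.0):
                raise DegeneratePatchError(
                    f"white-patch channel mean {m} outside (0, 255]"
                )


def measure_white_patch(image: np.ndarray, card_geometry: CardGeometry) -> WhitePatchStats:
    """Average the white patch of the calibration card on the uncalibrated image.

    Raises
    ------
    DegeneratePatchError
        If the patch region is empty or any channel averages to zero.
    ValueError
        If the patch bbox does not lie inside the image.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be HxWx3")
    r0, r1, c0, c1 = card_geometry.patch_bboxes["white"]
    h, w = image.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError("white patch bbox lies outside the image")
    patch = image[r0:r1, c0:c1].reshape(-1, 3).astype(float)
    if patch.shape[0] == 0:
        raise DegeneratePatchError("white patch region is empty")
    mean = patch.mean(axis=0)
    if np.any(mean <= 0):
        raise DegeneratePatchError(
            "a white-patch channel mean is zero; the diagonal transform is undefined"
        )
    return WhitePatchStats(mean_rgb=tuple(float(m) for m in mean),
                           pixel_count=patch.shape[0])


def apply_white_balance(image: np.ndarray, stats: WhitePatchStats) -> np.ndarray:
    """Apply the diagonal white-balance transform; returns a uint8 image.

    Each channel value c becomes ``clip(round(255 / mean_c * c), 0, 255)``
    with round-half-up, so the white patch itself maps exactly to
    (255, 255, 255) and the transform is monotone non-decreasing per channel.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be HxWx3")
    # multiply before dividing so exact halves (e.g. 255*100/200) stay exact
    out = np.floor(image.astype(float) * 255.0
                   / np.asarray(stats.mean_rgb, dtype=float) + 0.5)
    return np.clip(out, 0.0, 255.0).astype(np.uint8)


def calibrate(image: np.ndarray, card_geometry: CardGeometry) -> np.ndarray:
    """Measure the white patch and white-balance the image in one step."""
    return apply_white_balance(image, measure_white_patch(image, card_geometry))
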