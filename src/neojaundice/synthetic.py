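"""Seeded synthetic face-like scenes emulating a smartphone jaundice-screening cohort.

The clinical data this package was designed around (forehead/sclera photographs
of neonates with transcutaneous-bilirubin ground truth) is private, so the
generator builds scenes with the same statistical structure the analysis
assumes: a skin region and two sclera regions whose color shifts toward yellow
(a blue-channel depression) with a latent bilirubin level, a calibration card
with a known white patch, a per-image diagonal illumination gain, additive
pixel noise, and a threshold labeling rule (TCB >= 204 umol/L -> jaundiced).

Yellowing is modeled as a linear blue-channel drop because, in RGB, yellow is
the complement of blue: the clinical yellow cast of jaundiced skin and sclera
corresponds to attenuated blue reflectance at roughly constant red/green.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "TCB_THRESHOLD",
    "TCB_NORMALIZATION",
    "HEALTHY_TCB_RANGE",
    "JAUNDICED_TCB_RANGE",
    "CardGeometry",
    "SceneParams",
    "SyntheticScene",
    "TabularCohort",
    "label_from_tcb",
    "canonical_landmark_points",
    "default_card_geometry",
    "generate_scene",
    "generate_cohort",
    "generate_tabular",
    "quantize_gains",
    "write_scene",
    "read_scene_image",
    "write_cohort",
]

#: TCB level (umol/L) at or above which a neonate is labeled jaundiced.
TCB_THRESHOLD = 204.0

#: TCB scale used to normalize bilirubin into [0, 1] for the color-effect model.
TCB_NORMALIZATION = 300.0

#: Uniform TCB draw ranges (umol/L) for the two classes.
HEALTHY_TCB_RANGE = (0.0, 203.0)
JAUNDICED_TCB_RANGE = (204.0, 300.0)


class GeometryError(ValueError):
    """Scene geometry is inconsistent (card overlaps an ROI, layout outside image...)."""


def label_from_tcb(tcb: float) -> str:
    """Binary diagnosis label from a transcutaneous bilirubin level.

    Parameters
    ----------
    tcb : float
        TCB in umol/L; must be non-negative.

    Returns
    -------
    str
        ``"jaundiced"`` when ``tcb >= 204``, else ``"healthy"``.
    """
    if not np.isfinite(tcb) or tcb < 0:
        raise ValueError(f"tcb must be a finite non-negative level, got {tcb!r}")
    return "jaundiced" if tcb >= TCB_THRESHOLD else "healthy"


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class CardGeometry:
    """Calibration-card layout: card bounding box and named reference patches.

    Rectangles are ``(row_start, row_stop, col_start, col_stop)`` half-open in
    pixel coordinates.  One patch must be named ``"white"`` with reference
    color (255, 255, 255); its observed average color defines the per-channel
    white-balance gains.
    """

    card_bbox: tuple[int, int, int, int]
    patch_bboxes: dict[str, tuple[int, int, int, int]]
    patch_reference_colors: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if "white" not in self.patch_bboxes:
            raise GeometryError("card must contain a patch named 'white'")
        if tuple(self.patch_reference_colors.get("white", ())) != (255.0, 255.0, 255.0):
            raise GeometryError("the 'white' patch reference color must be (255, 255, 255)")
        r0, r1, c0, c1 = self.card_bbox
        for name, (pr0, pr1, pc0, pc1) in self.patch_bboxes.items():
            if not (r0 <= pr0 < pr1 <= r1 and c0 <= pc0 < pc1 <= c1):
                raise GeometryError(f"patch {name!r} lies outside the card bbox")

    def to_dict(self) -> dict:
        return {
            "card_bbox": list(self.card_bbox),
            "patch_bboxes": {k: list(v) for k, v in self.patch_bboxes.items()},
            "patch_reference_colors": {
                k: list(v) for k, v in self.patch_reference_colors.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CardGeometry":
        return cls(
            card_bbox=tuple(d["card_bbox"]),
            patch_bboxes={k: tuple(v) for k, v in d["patch_bboxes"].items()},
            patch_reference_colors={
                k: tuple(float(x) for x in v)
                for k, v in d["patch_reference_colors"].items()
            },
        )


def default_card_geometry(image_height: int = 256, image_width: int = 256) -> CardGeometry:
    """Card on the chest below the face: four reference patches in a row."""
    r0, r1 = round(0.845 * image_height), round(0.97 * image_height)
    c0, c1 = round(0.25 * image_width), round(0.75 * image_width)
    names = ["white", "light_gray", "dark_gray", "tan"]
    colors = {
        "white": (255.0, 255.0, 255.0),
        "light_gray": (160.0, 160.0, 160.0),
        "dark_gray": (96.0, 96.0, 96.0),
        "tan": (200.0, 150.0, 100.0),
    }
    margin = 4
    inner_w = (c1 - c0) - 2 * margin
    cell = inner_w // 4
    patches = {}
    for i, name in enumerate(names):
        pc0 = c0 + margin + i * cell
        patches[name] = (r0 + margin, r1 - margin, pc0 + 2, pc0 + cell - 2)
    return CardGeometry(card_bbox=(r0, r1, c0, c1), patch_bboxes=patches,
                        patch_reference_colors=colors)


def quantize_gains(gains: Sequence[float]) -> tuple[float, float, float]:
    """Snap illumination gains to the 1/255 grid.

    A gain of m/255 maps an ideal white surface to the exact 8-bit level m,
    so 8-bit painting followed by white-balance recalibration loses at most
    one intensity unit to rounding.
    """
    out = []
    for g in gains:
        m = round(g * 255.0)
        if m < 1:
            raise ValueError(f"gain {g} too small to quantize")
        out.append(m / 255.0)
    return tuple(out)


@dataclass(frozen=True)
class SceneParams:
    """Generator parameters for one synthetic scene.

    ``jaundice_blue_drop`` is the blue-channel depression (intensity units)
    applied to skin and sclera at the full normalized bilirubin level
    (``tcb / 300``); the default 60 yields a ~30-unit separation between the
    class mean colors under the default TCB draw ranges.
    """

    image_height: int = 256
    image_width: int = 256
    skin_base_color: tuple[float, float, float] = (225.0, 180.0, 160.0)
    sclera_base_color: tuple[float, float, float] = (250.0, 248.0, 244.0)
    jaundice_blue_drop: float = 60.0
    illumination_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sigma: float = 10.0
    card_geometry: CardGeometry | None = None
    tcb: float = 0.0
    seed: int = 0
    occlude: bool = False

    def __post_init__(self) -> None:
        for g in self.illumination_gains:
            if not (0.0 < g <= 1.0):
                raise ValueError(f"illumination gains must lie in (0, 1], got {g}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.jaundice_blue_drop < 0:
            raise ValueError("jaundice_blue_drop must be >= 0")
        if not np.isfinite(self.tcb) or self.tcb < 0:
            raise ValueError("tcb must be finite and >= 0")
        if self.image_height < 224 or self.image_width < 224:
            raise ValueError("scene layout requires at least a 224x224 canvas")

    @property
    def card(self) -> CardGeometry:
        return self.card_geometry or default_card_geometry(
            self.image_height, self.image_width
        )


# 68-point layout fractions (of width/height); eyes and eyebrows carry the
# analysis, the remaining points just sketch a plausible frontal face.
_BROW_ROW = 0.655
_EYE_ROW_OFFSET = 0.09
_EYE_DCOL = 0.13
_EYE_A = 0.091   # sclera ellipse semi-axis along columns
_EYE_B = 0.0392  # semi-axis along rows
_LANDMARK_SCALE = 1.03  # eye landmarks sit just outside the painted ellipse

_FACE_BOX = (0.06, 0.82, 0.16, 0.84)  # row0, row1, col0, col1 fractions
_BACKGROUND = (90.0, 95.0, 105.0)
_CARD_BASE = (30.0, 30.0, 30.0)


def _eye_centers(h: int, w: int) -> tuple[tuple[float, float], tuple[float, float]]:
    cy = _BROW_ROW * h + _EYE_ROW_OFFSET * h
    cx = w / 2.0
    right = (cy, cx - _EYE_DCOL * w)   # subject's right eye = viewer left
    left = (cy, cx + _EYE_DCOL * w)
    return right, left


def _eye_axes(h: int, w: int) -> tuple[float, float]:
    return _EYE_B * h, _EYE_A * w  # (row semi-axis, col semi-axis)


def canonical_landmark_points(image_height: int = 256, image_width: int = 256) -> np.ndarray:
    """68 (col, row) landmark points in the standard 0-based convention.

    Indices 17-26 are the eyebrows, 36-41 the right eye, 42-47 the left eye;
    the eye hexagons are placed on a 1.05-scaled copy of the painted sclera
    ellipses so their convex hull closely covers the painted region.
    """
    h, w = image_height, image_width
    pts = np.zeros((68, 2), dtype=float)  # (col, row)
    cx = w / 2.0
    brow_row = _BROW_ROW * h
    (rc, rx), (lc, lx) = _eye_centers(h, w)
    b_ax, a_ax = _eye_axes(h, w)

    # jaw 0-16: lower half of a face ellipse
    jaw_ry, jaw_rx = 0.26 * h, 0.33 * w
    jaw_cy = 0.56 * h
    for i in range(17):
        theta = np.pi * (1.0 - i / 16.0)  # pi .. 0, left side of image to right
        pts[i] = (cx - jaw_rx * np.cos(theta), jaw_cy + jaw_ry * np.sin(theta))

    # eyebrows 17-21 (right) and 22-26 (left), gentle arc above the eyes
    for i, t in enumerate(np.linspace(0.0, 1.0, 5)):
        col = cx - 0.24 * w + t * 0.18 * w
        pts[17 + i] = (col, brow_row - 2.0 * np.sin(np.pi * t))
    for i, t in enumerate(np.linspace(0.0, 1.0, 5)):
        col = cx + 0.06 * w + t * 0.18 * w
        pts[22 + i] = (col, brow_row - 2.0 * np.sin(np.pi * t))

    # nose 27-35
    nose_top = brow_row + 0.02 * h
    for i in range(4):  # bridge 27-30
        pts[27 + i] = (cx, nose_top + i * 0.035 * h)
    base_row = nose_top + 0.14 * h
    for i, dc in enumerate((-0.04, -0.02, 0.0, 0.02, 0.04)):  # nostrils 31-35
        pts[31 + i] = (cx + dc * w, base_row)

    # eyes 36-47: hexagon vertices at 180/120/60/0/300/240 degrees
    angles = np.deg2rad([180.0, 120.0, 60.0, 0.0, 300.0, 240.0])
    s = _LANDMARK_SCALE
    for base, (ecy, ecx) in ((36, (rc, rx)), (42, (lc, lx))):
        for k, th in enumerate(angles):
            pts[base + k] = (ecx + s * a_ax * np.cos(th), ecy - s * b_ax * np.sin(th))

    # mouth 48-67: two concentric ellipses
    mouth_cy, mouth_rx, mouth_ry = 0.795 * h, 0.10 * w, 0.028 * h
    for i in range(12):  # outer 48-59
        th = np.pi - 2.0 * np.pi * i / 12.0
        pts[48 + i] = (cx - mouth_rx * np.cos(th), mouth_cy + mouth_ry * np.sin(th))
    for i in range(8):  # inner 60-67
        th = np.pi - 2.0 * np.pi * i / 8.0
        pts[60 + i] = (cx - 0.6 * mouth_rx * np.cos(th), mouth_cy + 0.6 * mouth_ry * np.sin(th))

    pts = np.rint(pts)
    pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
    return pts.astype(int)


@dataclass
class SyntheticScene:
    """A generated scene plus its ground truth."""

    image: np.ndarray                      # H x W x 3 uint8
    landmarks: "np.ndarray"                # 68 x 2 int, (col, row)
    true_skin_color: tuple[float, float, float]     # post-bilirubin, pre-illumination
    true_sclera_color: tuple[float, float, float]
    tcb: float
    label: str
    params: SceneParams

    @property
    def card_geometry(self) -> CardGeometry:
        return self.params.card

    def region_masks(self) -> dict[str, np.ndarray]:
        """Ground-truth painted regions: ``skin``, ``left_sclera``, ``right_sclera``."""
        h, w = self.params.image_height, self.params.image_width
        skin = np.zeros((h, w), dtype=bool)
        r0, r1, c0, c1 = _face_box_px(h, w)
        skin[r0:r1, c0:c1] = True
        (rc, rx), (lc, lx) = _eye_centers(h, w)
        b_ax, a_ax = _eye_axes(h, w)
        masks = {}
        for name, (ecy, ecx) in (("right_sclera", (rc, rx)), ("left_sclera", (lc, lx))):
            m = np.zeros((h, w), dtype=bool)
            rr, cc = _draw_ellipse(ecy, ecx, b_ax, a_ax, shape=(h, w))
            m[rr, cc] = True
            masks[name] = m
            skin &= ~m
        masks["skin"] = skin
        return masks


def _face_box_px(h: int, w: int) -> tuple[int, int, int, int]:
    return (round(_FACE_BOX[0] * h), round(_FACE_BOX[1] * h),
            round(_FACE_BOX[2] * w), round(_FACE_BOX[3] * w))


def _shifted(color: Sequence[float], tcb: float, drop: float) -> tuple[float, float, float]:
    # ground-truth region colors are 8-bit camera colors: quantize the
    # bilirubin-shifted value so painting adds no second rounding error
    frac = min(tcb / TCB_NORMALIZATION, 1.0)
    r, g, b = color
    out = np.clip([r, g, b - drop * frac], 0, 255)
    return tuple(float(v) for v in np.floor(out + 0.5))


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render one scene: paint regions, apply illumination, add noise, quantize.

    The painted skin and sclera colors are the base colors with the blue
    channel depressed by ``jaundice_blue_drop * min(tcb/300, 1)``; every pixel
    is then multiplied channel-wise by the illumination gains, Gaussian noise
    of ``noise_sigma`` is added, and the result is clipped to [0, 255] and
    rounded half-up to uint8.  Regeneration with the same params (seed
    included) is bit-exact.
    """
    h, w = params.image_height, params.image_width
    card = params.card

    # card must not overlap the face box (which contains every ROI)
    fr0, fr1, fc0, fc1 = _face_box_px(h, w)
    r0, r1, c0, c1 = card.card_bbox
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise GeometryError("card bbox outside image bounds")
    if r0 < fr1 and r1 > fr0 and c0 < fc1 and c1 > fc0:
        raise GeometryError("calibration card overlaps the face region")

    skin_color = _shifted(params.skin_base_color, params.tcb, params.jaundice_blue_drop)
    sclera_color = _shifted(params.sclera_base_color, params.tcb, params.jaundice_blue_drop)

    canvas = np.empty((h, w, 3), dtype=float)
    canvas[:] = _BACKGROUND
    canvas[fr0:fr1, fc0:fc1] = skin_color
    (rc, rx), (lc, lx) = _eye_centers(h, w)
    b_ax, a_ax = _eye_axes(h, w)
    for ecy, ecx in ((rc, rx), (lc, lx)):
        rr, cc = _draw_ellipse(ecy, ecx, b_ax, a_ax, shape=(h, w))
        canvas[rr, cc] = sclera_color
    canvas[r0:r1, c0:c1] = _CARD_BASE
    for name, (pr0, pr1, pc0, pc1) in card.patch_bboxes.items():
        canvas[pr0:pr1, pc0:pc1] = card.patch_reference_colors[name]
    if params.occlude:
        canvas[fr0:fr1, fc0:fc1] = _BACKGROUND  # e.g. a hand covering the face

    canvas *= np.asarray(params.illumination_gains, dtype=float)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        canvas = canvas + rng.normal(0.0, params.noise_sigma, size=canvas.shape)
    image = np.floor(np.clip(canvas, 0.0, 255.0) + 0.5).astype(np.uint8)

    return SyntheticScene(
        image=image,
        landmarks=canonical_landmark_points(h, w),
        true_skin_color=skin_color,
        true_sclera_color=sclera_color,
        tcb=params.tcb,
        label=label_from_tcb(params.tcb),
        params=params,
    )


def generate_cohort(
    n: int,
    jaundiced_fraction: float,
    params: SceneParams | None = None,
    seed: int = 0,
    sample_gains: bool = False,
    gain_range: tuple[float, float] = (0.5, 1.0),
) -> list[SyntheticScene]:
    """Seeded cohort of scenes with a controlled class mix.

    Exactly ``round(n * jaundiced_fraction)`` scenes are jaundiced; TCB is
    drawn uniformly from [0, 203] (healthy) or [204, 300] (jaundiced).  When
    ``sample_gains`` is set, each scene receives per-channel illumination
    gains drawn from ``gain_range`` and snapped to the 1/255 grid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= jaundiced_fraction <= 1.0):
        raise ValueError("jaundiced_fraction must lie in [0, 1]")
    template = params or SceneParams()
    n_j = round(n * jaundiced_fraction)
    rng = np.random.default_rng(seed)
    labels = np.array(["jaundiced"] * n_j + ["healthy"] * (n - n_j))
    rng.shuffle(labels)
    scenes = []
    for i, lab in enumerate(labels):
        lo, hi = JAUNDICED_TCB_RANGE if lab == "jaundiced" else HEALTHY_TCB_RANGE
        tcb = float(rng.uniform(lo, hi))
        overrides: dict = {"tcb": tcb, "seed": int(rng.integers(0, 2**31 - 1))}
        if sample_gains:
            gains = quantize_gains(rng.uniform(*gain_range, size=3))
            overrides["illumination_gains"] = gains
        scenes.append(generate_scene(dataclasses.replace(template, **overrides)))
    return scenes


@dataclass
class TabularCohort:
    """Two-class Gaussian feature cohort for exercising the classifier stage."""

    features: np.ndarray
    labels: np.ndarray
    class_means: np.ndarray     # 2 x d
    class_covariances: np.ndarray  # 2 x d x d
    seed: int


def generate_tabular(
    n: int,
    d: int = 36,
    effect_size: float = 2.0,
    jaundiced_fraction: float = 0.5,
    seed: int = 0,
) -> TabularCohort:
    """Two spherical Gaussian classes separated by ``effect_size`` pooled SDs.

    The separation is along the normalized all-ones direction, so every
    feature carries an equal share of the signal.  ``effect_size=0`` makes the
    classes identically distributed.
    """
    if d not in (12, 24, 36):
        raise ValueError("d must be one of 12, 24, 36 (skin / eye / fused)")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= jaundiced_fraction <= 1.0):
        raise ValueError("jaundiced_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    direction = np.ones(d) / np.sqrt(d)
    mu0 = np.zeros(d)
    mu1 = effect_size * direction
    n1 = round(n * jaundiced_fraction)
    if n >= 2 and 0.0 < jaundiced_fraction < 1.0:
        n1 = min(max(n1, 1), n - 1)  # both classes represented
    n0 = n - n1
    x0 = rng.normal(size=(n0, d)) + mu0
    x1 = rng.normal(size=(n1, d)) + mu1
    features = np.vstack([x0, x1])
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    order = rng.permutation(n)
    cov = np.eye(d)
    return TabularCohort(
        features=features[order],
        labels=labels[order],
        class_means=np.stack([mu0, mu1]),
        class_covariances=np.stack([cov, cov]),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# disk IO: PNG + sidecar JSON per scene, manifest CSV per cohort


def write_scene(scene: SyntheticScene, image_path: str | Path) -> Path:
    """Write ``image.png`` plus an ``image.json`` sidecar; returns the sidecar path."""
    image_path = Path(image_path)
    iio.imwrite(image_path, scene.image)
    sidecar = image_path.with_suffix(".json")
    payload = {
        "landmarks": scene.landmarks.tolist(),
        "tcb": scene.tcb,
        "label": scene.label,
        "illumination_gains": list(scene.params.illumination_gains),
        "true_skin_color": list(scene.true_skin_color),
        "true_sclera_color": list(scene.true_sclera_color),
        "card_geometry": scene.card_geometry.to_dict(),
        "seed": scene.params.seed,
    }
    sidecar.write_text(json.dumps(payload, indent=1))
    return sidecar


def read_scene_image(image_path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a scene PNG and its sidecar JSON."""
    image_path = Path(image_path)
    image = iio.imread(image_path)
    meta = json.loads(image_path.with_suffix(".json").read_text())
    return image, meta


def write_cohort(scenes: Iterable[SyntheticScene], out_dir: str | Path) -> Path:
    """Write every scene plus a ``manifest.csv`` (image, landmarks, card, tcb, label)."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, scene in enumerate(scenes):
        name = f"scene_{i:04d}.png"
        sidecar = write_scene(scene, out_dir / name)
        rows.append({
            "subject_id": f"subject_{i:04d}",
            "image_path": name,
            "landmark_path": sidecar.name,
            "card_path": sidecar.name,
            "tcb": scene.tcb,
            "label": scene.label,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
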