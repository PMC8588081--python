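"""Generator contracts: labeling rule, painting model, determinism, cohorts."""

import dataclasses

import numpy as np
import pytest

import neojaundice as nj
from neojaundice.synthetic import (
    GeometryError,
    default_card_geometry,
    quantize_gains,
)


@pytest.mark.parametrize("tcb,expected", [
    (204.0, "jaundiced"),
    (203.9, "healthy"),
    (0.0, "healthy"),
    (280.0, "jaundiced"),
])
def test_label_is_pure_threshold(tcb, expected):
    assert nj.label_from_tcb(tcb) == expected


def test_label_rejects_negative_tcb():
    with pytest.raises(ValueError):
        nj.label_from_tcb(-1.0)


def test_clean_scene_region_means_equal_base_colors(clean_scene):
    """No gain, no noise, no bilirubin: painted regions are bit-exact."""
    masks = clean_scene.region_masks()
    img = clean_scene.image
    assert np.array_equal(
        np.unique(img[masks["skin"]], axis=0), [[225, 180, 160]])
    for side in ("left_sclera", "right_sclera"):
        assert np.array_equal(
            np.unique(img[masks[side]], axis=0), [[250, 248, 244]])


def test_white_patch_under_uniform_gain():
    """Reference white times gain 0.8 paints as round(0.8*255)=204 on each channel."""
    scene = nj.generate_scene(nj.SceneParams(
        noise_sigma=0.0, illumination_gains=(0.8, 0.8, 0.8)))
    r0, r1, c0, c1 = scene.card_geometry.patch_bboxes["white"]
    assert np.array_equal(
        np.unique(scene.image[r0:r1, c0:c1].reshape(-1, 3), axis=0), [[204, 204, 204]])


def test_blue_channel_depression_is_linear_in_normalized_tcb():
    """tcb=250 with drop 60 and tcb/300 normalization lowers blue by 50."""
    scene = nj.generate_scene(nj.SceneParams(
        noise_sigma=0.0, tcb=250.0, jaundice_blue_drop=60.0))
    masks = scene.region_masks()
    skin = np.unique(scene.image[masks["skin"]], axis=0)
    assert np.array_equal(skin, [[225, 180, 160 - 50]])
    assert scene.true_sclera_color[2] == 244 - 50
    assert scene.label == "jaundiced"


def test_scene_regeneration_is_bit_exact():
    p = nj.SceneParams(noise_sigma=10.0, tcb=150.0, seed=99)
    a = nj.generate_scene(p)
    b = nj.generate_scene(p)
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.landmarks, b.landmarks)


def test_card_overlapping_face_raises():
    h = w = 256
    bad_card = default_card_geometry(h, w)
    shifted = dataclasses.replace(
        bad_card,
        card_bbox=(100, 136, 64, 192),
        patch_bboxes={k: (104, 132, c0, c1) for k, (_, _, c0, c1)
                      in bad_card.patch_bboxes.items()},
    )
    with pytest.raises(GeometryError):
        nj.generate_scene(nj.SceneParams(card_geometry=shifted))


def test_cohort_class_counts_match_fraction():
    scenes = nj.generate_cohort(68, 24 / 68, seed=0,
                                params=nj.SceneParams(noise_sigma=0.0))
    labels = [s.label for s in scenes]
    assert labels.count("jaundiced") == 24
    assert labels.count("healthy") == 44
    for s in scenes:
        lo, hi = (204, 300) if s.label == "jaundiced" else (0, 203)
        assert lo <= s.tcb <= hi


def test_cohort_all_healthy_and_determinism():
    a = nj.generate_cohort(10, 0.0, seed=5, params=nj.SceneParams(noise_sigma=0.0))
    assert all(s.label == "healthy" for s in a)
    b = nj.generate_cohort(10, 0.0, seed=5, params=nj.SceneParams(noise_sigma=0.0))
    assert [s.tcb for s in a] == [s.tcb for s in b]


def test_quantized_gains_map_white_to_integer_level():
    gains = quantize_gains((0.5004, 0.7, 0.99))
    for g in gains:
        assert float(g * 255).is_integer()


def test_occlusion_erases_face_regions():
    scene = nj.generate_scene(nj.SceneParams(noise_sigma=0.0, occlude=True))
    masks = scene.region_masks()
    assert np.array_equal(np.unique(scene.image[masks["skin"]], axis=0), [[90, 95, 105]])


class TestTabular:
    def test_zero_effect_classes_identically_distributed(self):
        c = nj.generate_tabular(4000, d=12, effect_size=0.0, seed=3)
        m0 = c.features[c.labels == 0].mean(axis=0)
        m1 = c.features[c.labels == 1].mean(axis=0)
        assert np.linalg.norm(m0 - m1) < 0.25
        assert np.array_equal(c.class_means[0], c.class_means[1])

    def test_effect_size_recovered_from_samples(self):
        c = nj.generate_tabular(200, d=36, effect_size=5.0, seed=4)
        x0, x1 = c.features[c.labels == 0], c.features[c.labels == 1]
        delta = x1.mean(axis=0) - x0.mean(axis=0)
        pooled_sd = np.sqrt((x0.var(ddof=1, axis=0).mean()
                             + x1.var(ddof=1, axis=0).mean()) / 2)
        observed = np.linalg.norm(delta) / pooled_sd
        assert abs(observed - 5.0) / 5.0 < 0.2

    def test_same_seed_reproduces_matrix(self):
        a = nj.generate_tabular(50, d=24, effect_size=1.0, seed=8)
        b = nj.generate_tabular(50, d=24, effect_size=1.0, seed=8)
        assert np.array_equal(a.features, b.features)
        assert np.array_equal(a.labels, b.labels)

    def test_invalid_dimension_rejected(self):
        with pytest.raises(ValueError):
            nj.generate_tabular(50, d=13, effect_size=1.0)


def test_scene_roundtrip_on_disk(tmp_path, clean_scene):
    from neojaundice.synthetic import read_scene_image, write_scene

    write_scene(clean_scene, tmp_path / "scene.png")
    image, meta = read_scene_image(tmp_path / "scene.png")
    assert np.array_equal(image, clean_scene.image)
    assert meta["label"] == "healthy"
    assert np.array_equal(np.asarray(meta["landmarks"]), clean_scene.landmarks)
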