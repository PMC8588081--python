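import numpy as np
import pandas as pd
import pytest

import neojaundice as nj


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, unit-gain scene with zero bilirubin."""
    return nj.generate_scene(nj.SceneParams(noise_sigma=0.0, tcb=0.0, seed=1))


@pytest.fixture(scope="session")
def clean_landmarks(clean_scene):
    return nj.LandmarkSet(clean_scene.landmarks, clean_scene.image.shape[:2])


def featurize_scenes(scenes):
    """Calibrate -> segment -> fused features for a list of scenes."""
    rows = []
    for i, s in enumerate(scenes):
        cal = nj.calibrate(s.image, s.card_geometry)
        masks = nj.segment_scene(nj.LandmarkSet(s.landmarks, s.image.shape[:2]))
        fv = nj.extract_scene_features(cal, masks, "fusion",
                                       subject_id=f"s{i:03d}", label=s.label)
        rec = dict(zip(fv.names, fv.values))
        rec["label"] = s.label
        rows.append(rec)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort_features():
    """40-scene noisy cohort with the default color-shift effect, featurized."""
    scenes = nj.generate_cohort(
        40, 0.4, params=nj.SceneParams(noise_sigma=10.0), seed=7, sample_gains=True)
    return featurize_scenes(scenes)


@pytest.fixture(scope="session")
def small_results(small_cohort_features):
    feats = small_cohort_features
    return nj.run_experiment(feats, feats["label"].to_numpy(), k=5, seed=3)
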