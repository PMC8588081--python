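"""Configured end-to-end pipeline: simulate -> calibrate -> segment -> featurize -> evaluate.

One manifest CSV (image path, landmark path, card path, tcb, label) is the
contract between stages, so each stage can be re-run independently off the
artifacts on disk.  A single master seed determines every stochastic choice.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import calibrate
from .evaluation import ComparisonResults, ScreeningExperiment
from .features import extract_scene_features
from .models import ModelConfig
from .segmentation import LandmarkSet, segment_scene
from .synthetic import CardGeometry, SceneParams, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("neojaundice")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and, when known, the subject id."""

    def __init__(self, stage: str, message: str, subject_id: str | None = None):
        self.stage = stage
        self.subject_id = subject_id
        where = f"stage {stage!r}" + (f", subject {subject_id!r}" if subject_id else "")
        super().__init__(f"{where}: {message}")


@dataclass
class PipelineConfig:
    """Paths, stage toggles and per-stage parameters for one pipeline run."""

    out_dir: Path
    n: int = 68
    jaundiced_fraction: float = 24 / 68
    sample_gains: bool = True
    noise_sigma: float = 10.0
    jaundice_blue_drop: float = 60.0
    stages: tuple[str, ...] = ("simulate", "calibrate", "segment", "featurize", "evaluate")
    feature_sets: tuple[str, ...] = ("skin", "eye", "fusion")
    models: tuple[str, ...] = ("mlp", "svm", "dt", "rf")
    k: int = 5
    alpha: float = 0.05
    seed: int = 0
    smote: str = "per_fold"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "feature_sets", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_seeds(master_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master_seed)
    names = ("simulate", "evaluate")
    return {name: int(s.generate_state(1)[0] % (2**31 - 1))
            for name, s in zip(names, ss.spawn(len(names)))}


def _manifest(cfg: PipelineConfig) -> pd.DataFrame:
    path = cfg.out_dir / "manifest.csv"
    if not path.exists():
        raise PipelineError("io", f"manifest not found at {path}; run the simulate "
                            "stage or point out_dir at an existing cohort")
    return pd.read_csv(path)


def _sidecar(cfg: PipelineConfig, row, stage: str) -> dict:
    path = cfg.out_dir / row.landmark_path
    if not path.exists():
        raise PipelineError(stage, f"missing landmark/sidecar file {path.name}",
                            subject_id=row.subject_id)
    return json.loads(path.read_text())


def run_pipeline(config: PipelineConfig) -> ComparisonResults | None:
    """Execute the toggled stages; returns the comparison results when the
    evaluate stage runs, else None.  Artifacts land under ``config.out_dir``."""
    cfg = config
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    results: ComparisonResults | None = None

    if "simulate" in cfg.stages:
        log.info("simulate: n=%d, jaundiced fraction %.3f", cfg.n, cfg.jaundiced_fraction)
        template = SceneParams(noise_sigma=cfg.noise_sigma,
                               jaundice_blue_drop=cfg.jaundice_blue_drop)
        scenes = generate_cohort(cfg.n, cfg.jaundiced_fraction, params=template,
                                 seed=seeds["simulate"], sample_gains=cfg.sample_gains)
        write_cohort(scenes, cfg.out_dir)

    manifest = _manifest(cfg)

    if "calibrate" in cfg.stages:
        cal_dir = cfg.out_dir / "calibrated"
        cal_dir.mkdir(exist_ok=True)
        for row in manifest.itertuples():
            meta = _sidecar(cfg, row, "calibrate")
            image = iio.imread(cfg.out_dir / row.image_path)
            try:
                card = CardGeometry.from_dict(meta["card_geometry"])
                out = calibrate(image, card)
            except Exception as exc:
                raise PipelineError("calibrate", str(exc), subject_id=row.subject_id)
            iio.imwrite(cal_dir / row.image_path, out)
        log.info("calibrate: %d images -> %s", len(manifest), cal_dir)

    if "segment" in cfg.stages:
        mask_dir = cfg.out_dir / "masks"
        mask_dir.mkdir(exist_ok=True)
        for row in manifest.itertuples():
            meta = _sidecar(cfg, row, "segment")
            shape = iio.imread(cfg.out_dir / row.image_path).shape[:2]
            try:
                masks = segment_scene(LandmarkSet(np.asarray(meta["landmarks"]), shape))
            except Exception as exc:
                raise PipelineError("segment", str(exc), subject_id=row.subject_id)
            for name, rm in masks.items():
                iio.imwrite(mask_dir / f"{row.subject_id}_{name}.png",
                            rm.mask.astype(np.uint8) * 255)
        log.info("segment: masks -> %s", mask_dir)

    if "featurize" in cfg.stages:
        rows = []
        for row in manifest.itertuples():
            meta = _sidecar(cfg, row, "featurize")
            cal_path = cfg.out_dir / "calibrated" / row.image_path
            if not cal_path.exists():
                raise PipelineError("featurize", "calibrated image missing; run the "
                                    "calibrate stage first", subject_id=row.subject_id)
            image = iio.imread(cal_path)
            try:
                masks = segment_scene(LandmarkSet(np.asarray(meta["landmarks"]),
                                                  image.shape[:2]))
                fv = extract_scene_features(image, masks, "fusion",
                                            subject_id=row.subject_id, label=row.label)
            except Exception as exc:
                raise PipelineError("featurize", str(exc), subject_id=row.subject_id)
            rec = dict(zip(fv.names, fv.values))
            rec["subject_id"] = row.subject_id
            rec["label"] = row.label
            rows.append(rec)
        feats = pd.DataFrame(rows)
        feats.to_csv(cfg.out_dir / "features.csv", index=False,
                     float_format="%.10g")
        log.info("featurize: %d subjects -> features.csv", len(feats))

    if "evaluate" in cfg.stages:
        feat_path = cfg.out_dir / "features.csv"
        if not feat_path.exists():
            raise PipelineError("evaluate", "features.csv missing; run featurize first")
        feats = pd.read_csv(feat_path)
        labels = feats["label"].to_numpy()
        configs = {name: ModelConfig(name) for name in cfg.models}
        exp = ScreeningExperiment(feats, labels, feature_sets=cfg.feature_sets,
                                  model_configs=configs, k=cfg.k, alpha=cfg.alpha,
                                  smote=cfg.smote)
        results = exp.fit(seed=seeds["evaluate"])
        results.to_csv(cfg.out_dir / "report")
        log.info("evaluate: report -> %s", cfg.out_dir / "report")

    run_manifest = {
        "version": __version__,
        "master_seed": cfg.seed,
        "stage_seeds": seeds,
        "stages": list(cfg.stages),
        "n": cfg.n,
        "jaundiced_fraction": cfg.jaundiced_fraction,
    }
    (cfg.out_dir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1))
    return results
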