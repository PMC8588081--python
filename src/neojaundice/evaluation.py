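"""Cross-validated model comparison: SMOTE, stratified k-fold, five metrics,
and the k-fold cross-validated paired t-test.

The protocol: features are split into stratified folds once per experiment
(the same folds for every model and feature set, so per-fold performance
differences are properly paired); within each training fold the minority
class is oversampled with SMOTE, the model is fitted, and accuracy,
macro-precision, macro-recall, macro-F1 and AUC are measured on the untouched
test fold.  Oversampling inside the training fold (rather than before the
split) keeps synthetic copies of test subjects out of the training data; the
pre-split variant is available as ``smote="pre_cv"`` for comparison.

Two models A and B are compared with the k-fold cross-validated paired
t-test on their per-fold performance differences p_i = p_Ai - p_Bi:

    t = p_bar * sqrt(k) / sqrt(sum_i (p_i - p_bar)^2 / (k - 1)),  df = k - 1

with a two-sided p-value.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .models import ModelConfig, TrainedModel, positive_scores, train_model

__all__ = [
    "FoldMetrics",
    "PairedTestResult",
    "smote_balance",
    "stratified_kfold_split",
    "compute_metrics",
    "cv_paired_ttest",
    "ScreeningExperiment",
    "ComparisonResults",
    "run_experiment",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


# ---------------------------------------------------------------------------
# SMOTE


def smote_balance(
    features: np.ndarray,
    labels: Sequence,
    seed: int = 0,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by synthetic minority oversampling.

    Each synthetic sample is a convex combination ``x + t * (nb - x)`` of a
    random minority sample x and one of its ``k_neighbors`` nearest
    minority-class neighbors nb, with t ~ U(0, 1).  ``k_neighbors`` is
    reduced automatically when the minority class is small; a single-sample
    minority cannot be interpolated and raises.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be 2-D with one row per label")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"SMOTE balancing expects 2 classes, got {classes.size}")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_min = int(counts.min())
    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples to interpolate")
    deficit = int(counts.max() - n_min)
    k = min(k_neighbors, n_min - 1)
    Xmin = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    neighbor_idx = nn.kneighbors(Xmin, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=deficit)
    pick = rng.integers(0, k, size=deficit)
    t = rng.uniform(0.0, 1.0, size=deficit)
    anchors = Xmin[base]
    partners = Xmin[neighbor_idx[base, pick]]
    synthetic = anchors + t[:, None] * (partners - anchors)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(deficit, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# folds and metrics


def stratified_kfold_split(labels: Sequence, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """k disjoint stratified test-index sets covering every sample once."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


@dataclass(frozen=True)
class FoldMetrics:
    """The five evaluation metrics for one test fold, all in [0, 1]."""

    fold_id: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float

    def as_dict(self) -> dict:
        return {"fold": self.fold_id, **{m: getattr(self, m) for m in METRIC_NAMES}}


def compute_metrics(
    true_labels: Sequence,
    predicted_labels: Sequence,
    scores: Sequence,
    fold_id: int = 0,
    positive=None,
    averaging: str = "macro",
) -> FoldMetrics:
    """Accuracy, precision, recall, F1 and AUC for one fold.

    Precision/recall/F1 are macro-averaged by default (both classes weigh
    equally; macro-recall equals balanced accuracy), switchable to
    positive-class binary averaging.  AUC is the probability that a random
    jaundiced sample scores above a random healthy one, ties counting 1/2;
    ``scores`` must be jaundiced-class probabilities.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    s = np.asarray(scores, dtype=float)
    if not (len(y_true) == len(y_pred) == len(s)):
        raise ValueError("true labels, predictions and scores must align")
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("AUC is undefined when one class is absent from true labels")
    if positive is None:
        positive = "jaundiced" if "jaundiced" in classes else classes[-1]
    if averaging == "macro":
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0)
    elif averaging == "binary":
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="binary", pos_label=positive, zero_division=0)
    else:
        raise ValueError("averaging must be 'macro' or 'binary'")
    return FoldMetrics(
        fold_id=fold_id,
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        auc=float(roc_auc_score(y_true == positive, s)),
    )


# ---------------------------------------------------------------------------
# paired test


@dataclass(frozen=True)
class PairedTestResult:
    """k-fold cross-validated paired t-test between two models' fold scores."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    per_fold_differences: tuple[float, ...]
    mean_difference: float
    degenerate: bool = False


def cv_paired_ttest(scores_a: Sequence[float], scores_b: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test on per-fold performance differences.

    Zero-variance differences are degenerate: t=0/p=1 when the means also
    agree, otherwise the difference is deterministic and reported as
    t=+/-inf, p=0 with the ``degenerate`` flag set.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D and equally long")
    k = a.size
    if k < 2:
        raise ValueError("need k >= 2 folds")
    d = a - b
    d_bar = float(d.mean())
    ss = float(((d - d_bar) ** 2).sum())
    df = k - 1
    if ss == 0.0:
        if d_bar == 0.0:
            return PairedTestResult(0.0, df, 1.0, tuple(d), d_bar)
        t = float(np.sign(d_bar) * np.inf)
        return PairedTestResult(t, df, 0.0, tuple(d), d_bar, degenerate=True)
    s = np.sqrt(ss / df)
    t = d_bar * np.sqrt(k) / s
    p = 2.0 * float(_stats.t.sf(abs(t), df))
    return PairedTestResult(float(t), df, p, tuple(d), d_bar)


# ---------------------------------------------------------------------------
# the experiment / results objects


class ScreeningExperiment:
    """Cross-validated comparison of classifiers across feature sets.

    Parameters
    ----------
    features : DataFrame
        One row per subject; columns named ``<roi>_<space>_<channel>`` as
        produced by the feature-extraction stage (``skin_*``, ``left_eye_*``,
        ``right_eye_*``).  Extra columns ``subject_id`` / ``label`` are
        ignored as features.
    labels : sequence
        Binary class labels aligned with the rows.
    feature_sets : sequence of {"skin", "eye", "fusion"}
    model_configs : mapping of name -> ModelConfig, default the four
        traditional models with the study hyperparameters.
    k : folds (default 5); alpha : significance level for the pairwise table.
    smote : "per_fold" (default; oversample inside each training fold) or
        "pre_cv" (oversample once before splitting) or "off".
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: Sequence,
        feature_sets: Sequence[str] = ("skin", "eye", "fusion"),
        model_configs: dict[str, ModelConfig] | None = None,
        k: int = 5,
        alpha: float = 0.05,
        smote: str = "per_fold",
        averaging: str = "macro",
    ) -> None:
        self.features = features.drop(
            columns=[c for c in ("subject_id", "label") if c in features.columns]
        )
        self.labels = np.asarray(labels)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must align")
        self.feature_sets = tuple(feature_sets)
        self.model_configs = model_configs or {
            kind: ModelConfig(kind) for kind in ("mlp", "svm", "dt", "rf")
        }
        self.k = int(k)
        self.alpha = float(alpha)
        if smote not in ("per_fold", "pre_cv", "off"):
            raise ValueError("smote must be 'per_fold', 'pre_cv' or 'off'")
        self.smote = smote
        self.averaging = averaging

    def _columns_for(self, feature_set: str) -> list[str]:
        prefixes = {
            "skin": ("skin_",),
            "eye": ("left_eye_", "right_eye_"),
            "fusion": ("skin_", "left_eye_", "right_eye_"),
        }[feature_set]
        cols = [c for c in self.features.columns if c.startswith(prefixes)]
        if not cols:
            raise ValueError(f"no feature columns found for set {feature_set!r}")
        return cols

    def fit(self, seed: int = 0) -> "ComparisonResults":
        """Run the full protocol; returns a results object with the tables."""
        ss = np.random.SeedSequence(seed)
        fold_seed, smote_seed_root, model_seed_root = (
            int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)
        )
        X_all = {fs: self.features[self._columns_for(fs)].to_numpy(float)
                 for fs in self.feature_sets}
        y = self.labels

        if self.smote == "pre_cv":
            # leaky variant kept for protocol comparison: oversample first,
            # then split the augmented data
            balanced = {}
            for fs in self.feature_sets:
                Xb, yb = smote_balance(X_all[fs], y, seed=smote_seed_root)
                balanced[fs] = (Xb, yb)
        rows = []
        fold_assignments: dict[str, list[np.ndarray]] = {}
        for fs in self.feature_sets:
            if self.smote == "pre_cv":
                X, y_fs = balanced[fs]
            else:
                X, y_fs = X_all[fs], y
            folds = stratified_kfold_split(y_fs, k=self.k, seed=fold_seed)
            fold_assignments[fs] = folds
            all_idx = np.arange(len(y_fs))
            for model_name, config in self.model_configs.items():
                for fold_id, test_idx in enumerate(folds):
                    train_idx = np.setdiff1d(all_idx, test_idx)
                    X_tr, y_tr = X[train_idx], y_fs[train_idx]
                    if self.smote == "per_fold":
                        X_tr, y_tr = smote_balance(
                            X_tr, y_tr,
                            seed=(smote_seed_root + 131 * fold_id) % (2**31 - 1))
                    name_tag = zlib.crc32(model_name.encode()) % 7919
                    cfg = config.with_seed(
                        (model_seed_root + 977 * fold_id + name_tag) % (2**31 - 1))
                    model = train_model(cfg, X_tr, y_tr)
                    y_pred = model.estimator.predict(X[test_idx])
                    s = positive_scores(model, X[test_idx])
                    fm = compute_metrics(y_fs[test_idx], y_pred, s, fold_id=fold_id,
                                         averaging=self.averaging)
                    rows.append({"feature_set": fs, "model": model_name,
                                 **fm.as_dict()})
        metrics = pd.DataFrame(rows)
        return ComparisonResults(metrics=metrics, alpha=self.alpha, k=self.k,
                                 seed=seed, experiment=self)


@dataclass
class ComparisonResults:
    """Per-fold metrics, their means, and the pairwise paired-test table."""

    metrics: pd.DataFrame          # long: feature_set, model, fold, 5 metrics
    alpha: float
    k: int
    seed: int
    experiment: ScreeningExperiment | None = None

    @property
    def mean_metrics(self) -> pd.DataFrame:
        """Fold-averaged metrics, one row per (feature_set, model)."""
        return (self.metrics
                .groupby(["feature_set", "model"], sort=False)[list(METRIC_NAMES)]
                .mean()
                .reset_index())

    def fold_scores(self, feature_set: str, model: str, metric: str) -> np.ndarray:
        sel = self.metrics[(self.metrics.feature_set == feature_set)
                           & (self.metrics.model == model)]
        return sel.sort_values("fold")[metric].to_numpy()

    def pairwise_tests(self, metrics: Sequence[str] = METRIC_NAMES) -> pd.DataFrame:
        """Paired t-tests for every within-feature-set model pair and every
        same-model pair of feature sets, for each requested metric."""
        combos = sorted(set(zip(self.metrics.feature_set, self.metrics.model)),
                        key=lambda t: (t[0], t[1]))
        pairs = []
        for i, (fs_a, m_a) in enumerate(combos):
            for fs_b, m_b in combos[i + 1:]:
                if fs_a == fs_b or m_a == m_b:
                    pairs.append(((fs_a, m_a), (fs_b, m_b)))
        rows = []
        for (fs_a, m_a), (fs_b, m_b) in pairs:
            for metric in metrics:
                res = cv_paired_ttest(self.fold_scores(fs_a, m_a, metric),
                                      self.fold_scores(fs_b, m_b, metric))
                rows.append({
                    "feature_set_a": fs_a, "model_a": m_a,
                    "feature_set_b": fs_b, "model_b": m_b,
                    "metric": metric, "t": res.t_statistic,
                    "df": res.degrees_of_freedom, "p": res.p_value,
                    "significant": res.p_value < self.alpha,
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary table of fold-averaged metrics."""
        mm = self.mean_metrics
        lines = [
            "Cross-validated screening comparison "
            f"(k={self.k}, alpha={self.alpha}, seed={self.seed})",
            "",
            f"{'Features':<10}{'Classifier':<12}" + "".join(f"{m.capitalize():>11}"
                                                            for m in METRIC_NAMES),
        ]
        for _, r in mm.iterrows():
            lines.append(f"{r.feature_set:<10}{r.model:<12}"
                         + "".join(f"{r[m]*100:>10.2f}%" for m in METRIC_NAMES))
        return "\n".join(lines)

    def to_csv(self, out_dir: str | Path) -> dict[str, Path]:
        """Write ``metrics.csv`` (table-style means), ``fold_metrics.csv`` and
        ``pairwise_tests.csv``; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        mm = self.mean_metrics.rename(columns={
            "feature_set": "Features", "model": "Classifier",
            "accuracy": "Accuracy", "precision": "Precision",
            "recall": "Recall", "f1": "F1", "auc": "AUC"})
        paths = {
            "metrics": out_dir / "metrics.csv",
            "fold_metrics": out_dir / "fold_metrics.csv",
            "pairwise_tests": out_dir / "pairwise_tests.csv",
        }
        mm.to_csv(paths["metrics"], index=False)
        self.metrics.to_csv(paths["fold_metrics"], index=False)
        self.pairwise_tests().to_csv(paths["pairwise_tests"], index=False)
        return paths


def run_experiment(
    features: pd.DataFrame,
    labels: Sequence,
    feature_sets: Sequence[str] = ("skin", "eye", "fusion"),
    model_configs: dict[str, ModelConfig] | None = None,
    k: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    smote: str = "per_fold",
) -> ComparisonResults:
    """Functional one-call wrapper around :class:`ScreeningExperiment`."""
    exp = ScreeningExperiment(features, labels, feature_sets=feature_sets,
                              model_configs=model_configs, k=k, alpha=alpha,
                              smote=smote)
    return exp.fit(seed=seed)
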