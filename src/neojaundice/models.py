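"""The four traditional classifiers plus the transfer-learning data contract.

Hyperparameters follow the study configuration: an MLP with two 200-unit
rectified-linear hidden layers trained with Adam for 50 epochs at batch 32;
an RBF-kernel SVM with C=1000 and gamma=0.7; a CART decision tree (gini,
unlimited depth, min split 2); and a 100-tree gini random forest.  SVM and
MLP see standardized features (training-fold statistics); trees get raw
features.  Standardization matters because an RBF kernel with gamma=0.7 on
raw 0-255 color scales would collapse every off-diagonal kernel entry to 0.

The transfer-learning branch is represented by its architecture contract
(:class:`DeepHeadSpec`) and its input pipeline (:func:`image_dataset_for_deep`,
which crops and composites the ROIs and balances classes by augmentation).
Gradient training of the convolutional branch is delegated to a user-supplied
backend; none is bundled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import resize as _resize, rotate as _rotate
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .segmentation import DegenerateROIError, LandmarkSet, segment_scene

__all__ = [
    "MODEL_KINDS",
    "ModelConfig",
    "DeepHeadSpec",
    "TrainedModel",
    "default_hyperparameters",
    "train_model",
    "predict_proba",
    "image_dataset_for_deep",
]

MODEL_KINDS = ("mlp", "svm", "dt", "rf", "deep")

_DEFAULT_HYPERPARAMETERS = {
    "mlp": {
        "hidden_layers": (200, 200),
        "activation": "relu",
        "optimizer": "adam",
        "epochs": 50,
        "batch_size": 32,
        # dropout 0.5 belongs to the study configuration; the sklearn backend
        # has no dropout, so regularization stays at its default L2 alpha
        "dropout": 0.5,
    },
    "svm": {"kernel": "rbf", "C": 1000.0, "gamma": 0.7},
    "dt": {"criterion": "gini", "max_depth": None, "min_samples_split": 2},
    "rf": {"n_estimators": 100, "criterion": "gini"},
    "deep": {"batch_size": 100, "epochs": 500, "momentum": 0.8, "optimizer": "sgd"},
}


def default_hyperparameters(model_kind: str) -> dict:
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}, got {model_kind!r}")
    return dict(_DEFAULT_HYPERPARAMETERS[model_kind])


@dataclass(frozen=True)
class ModelConfig:
    """A model kind, its hyperparameters (defaults filled in), and a seed."""

    model_kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        merged = default_hyperparameters(self.model_kind)
        unknown = set(self.hyperparameters) - set(merged)
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.model_kind}: {unknown}")
        merged.update(self.hyperparameters)
        object.__setattr__(self, "hyperparameters", merged)

    def with_seed(self, seed: int) -> "ModelConfig":
        return ModelConfig(self.model_kind, dict(self.hyperparameters), int(seed))


@dataclass(frozen=True)
class DeepHeadSpec:
    """Architecture contract for the transfer-learning classifier head.

    A convolutional backbone maps a 224x224x3 input to a 7x7x512 feature map;
    global average pooling reduces it to 512; three dense layers interleaved
    with two dropout layers (p=0.5) feed a softmax output.
    """

    input_size: tuple[int, int, int] = (224, 224, 3)
    backbone_output: tuple[int, int, int] = (7, 7, 512)
    pooled_size: int = 512
    dense_layers: int = 3
    dropout_layers: int = 2
    dropout_rate: float = 0.5
    output_activation: str = "softmax"


class PlattScaledSVC(BaseEstimator, ClassifierMixin):
    """RBF SVM with an explicit Platt-style probability link.

    Class probabilities are a logistic sigmoid of the signed SVM margin,
    fitted on the training margins, so ``predict_proba`` is guaranteed
    monotone in ``decision_function`` (libsvm's internal cross-validated
    estimates do not guarantee this on small or separable data).  Class
    predictions come from the SVM decision boundary itself.
    """

    def __init__(self, kernel="rbf", C=1.0, gamma="scale"):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma

    def fit(self, X, y):
        self.svc_ = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        margins = self.svc_.decision_function(X)
        self.link_ = LogisticRegression()
        self.link_.fit(margins.reshape(-1, 1), y)
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(X)

    def predict(self, X):
        return self.svc_.predict(X)

    def predict_proba(self, X):
        proba = self.link_.predict_proba(self.decision_function(X).reshape(-1, 1))
        # align the link's column order with the SVM's class order
        cols = [int(np.nonzero(self.link_.classes_ == c)[0][0]) for c in self.classes_]
        return proba[:, cols]


def _build_estimator(config: ModelConfig):
    hp = config.hyperparameters
    seed = config.seed
    if config.model_kind == "mlp":
        est = MLPClassifier(
            hidden_layer_sizes=tuple(hp["hidden_layers"]),
            activation=hp["activation"],
            solver=hp["optimizer"],
            batch_size=hp["batch_size"],
            max_iter=hp["epochs"],
            random_state=seed,
        )
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if config.model_kind == "svm":
        est = PlattScaledSVC(kernel=hp["kernel"], C=hp["C"], gamma=hp["gamma"])
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if config.model_kind == "dt":
        return DecisionTreeClassifier(
            criterion=hp["criterion"], max_depth=hp["max_depth"],
            min_samples_split=hp["min_samples_split"], random_state=seed,
        )
    if config.model_kind == "rf":
        return RandomForestClassifier(
            n_estimators=hp["n_estimators"], criterion=hp["criterion"],
            random_state=seed,
        )
    raise NotImplementedError(
        "the transfer-learning branch needs a convolutional backend supplied by "
        "the caller; this package ships the architecture contract (DeepHeadSpec) "
        "and the image pipeline (image_dataset_for_deep) only"
    )


@dataclass
class TrainedModel:
    """A fitted classifier exposing calibrated class probabilities."""

    model_kind: str
    estimator: object
    classes: np.ndarray
    n_features: int
    config: ModelConfig

    @property
    def positive_class(self):
        """The jaundiced class: ``"jaundiced"`` if present, else the largest label."""
        labels = list(self.classes)
        return "jaundiced" if "jaundiced" in labels else labels[-1]


def train_model(config: ModelConfig, features: np.ndarray, labels: Sequence) -> TrainedModel:
    """Fit one classifier; deterministic for a fixed config seed.

    Raises
    ------
    ValueError
        If the training set contains fewer than two classes or fewer than two
        samples of some class.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be 2-D with one row per label")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training samples")
    est = _build_estimator(config)
    with warnings.catch_warnings():
        # the study's fixed 50-epoch budget routinely stops before the sklearn
        # convergence tolerance is met; that is intended behavior
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return TrainedModel(model_kind=config.model_kind, estimator=est,
                        classes=classes, n_features=X.shape[1], config=config)


def predict_proba(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Per-sample class probabilities, columns ordered as ``model.classes``."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape} does not match training ({model.n_features})"
        )
    proba = model.estimator.predict_proba(X)
    return proba


def positive_scores(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Probability of the jaundiced class for each sample."""
    proba = predict_proba(model, features)
    idx = int(np.nonzero(model.classes == model.positive_class)[0][0])
    return proba[:, idx]


# ---------------------------------------------------------------------------
# transfer-learning input pipeline


def _crop_bbox(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    return image[rows.min(): rows.max() + 1, cols.min(): cols.max() + 1]


def _to_unit(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=float) / 255.0


def _compose(image: np.ndarray, masks: dict, feature_set: str,
             input_size: tuple[int, int]) -> np.ndarray:
    """ROI crops laid out on a fixed canvas, resized to ``input_size``; float [0,1]."""
    h, w = input_size
    if feature_set == "skin":
        return _resize(_to_unit(_crop_bbox(image, masks["forehead"].mask)), (h, w, 3),
                       anti_aliasing=True)
    if feature_set == "eye":
        canvas = np.zeros((h, w, 3))
        for i, key in enumerate(("left_sclera", "right_sclera")):
            crop = _resize(_to_unit(_crop_bbox(image, masks[key].mask)), (h, w // 2, 3),
                           anti_aliasing=True)
            canvas[:, i * (w // 2): (i + 1) * (w // 2)] = crop
        return canvas
    if feature_set == "fusion":
        canvas = np.zeros((h, w, 3))
        canvas[: h // 2] = _resize(_to_unit(_crop_bbox(image, masks["forehead"].mask)),
                                   (h // 2, w, 3), anti_aliasing=True)
        for i, key in enumerate(("left_sclera", "right_sclera")):
            crop = _resize(_to_unit(_crop_bbox(image, masks[key].mask)),
                           (h - h // 2, w // 2, 3), anti_aliasing=True)
            canvas[h // 2:, i * (w // 2): (i + 1) * (w // 2)] = crop
        return canvas
    raise ValueError(f"unknown feature_set {feature_set!r}")


def _augment(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = img
    if rng.random() < 0.5:
        out = out[:, ::-1]  # horizontal flip
    angle = rng.uniform(-10.0, 10.0)
    out = _rotate(out, angle, mode="edge")
    gain = rng.uniform(0.85, 1.15)  # brightness jitter
    return np.clip(out * gain, 0.0, 1.0)


def image_dataset_for_deep(
    scenes: Sequence,
    feature_set: str = "fusion",
    input_size: tuple[int, int] = (224, 224),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """ROI-crop image tensors plus labels, minority class balanced by augmentation.

    Per subject the ROIs are cropped from the (calibrated) image and
    composited on a fixed layout: the forehead alone (``skin``), the two
    sclera crops side by side (``eye``), or forehead on top with the scleras
    below (``fusion``), then resized to ``input_size``.  Flips, small
    rotations and brightness jitter replicate minority-class subjects until
    the classes balance.  Subjects whose ROIs are degenerate are skipped with
    a warning.
    """
    images, labels = [], []
    for i, scene in enumerate(scenes):
        try:
            masks = segment_scene(LandmarkSet(scene.landmarks, scene.image.shape[:2]))
        except DegenerateROIError as exc:
            warnings.warn(f"skipping scene {i}: {exc}", stacklevel=2)
            continue
        images.append(_compose(scene.image, masks, feature_set, input_size))
        labels.append(scene.label)
    X = np.stack(images)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size == 2 and counts[0] != counts[1]:
        rng = np.random.default_rng(seed)
        minority = classes[np.argmin(counts)]
        deficit = int(abs(counts[0] - counts[1]))
        pool = np.nonzero(y == minority)[0]
        extra = [_augment(X[rng.choice(pool)], rng) for _ in range(deficit)]
        X = np.concatenate([X, np.stack(extra)])
        y = np.concatenate([y, np.full(deficit, minority, dtype=y.dtype)])
    return X, y
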