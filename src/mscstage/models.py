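"""Staging models: CNN classifier/regressor and the classical baselines.

All models are scikit-learn-style estimators (``fit`` / ``predict`` /
``get_params``) over image tensors of shape (n, H, W, C) with values in
[0, 1], so they compose with sklearn model selection. Field-grouped
evaluation lives in :func:`evaluate_on_split`; every report records the
split it came from and the train/test field disjointness is asserted
before any metric is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Sequence

import numpy as np
from scipy import stats
from skimage.transform import resize
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier

from .features import texture_feature_table
from .segment import NucleusCrop
from .splits import FoldSplit, augment_rotations


@dataclass
class ModelSpec:
    """Configuration of one staging model run."""

    task: str = "classification"  # or "regression"
    input_channels: tuple[str, ...] = ("nucleus",)
    architecture: str = "small_cnn"  # or "large_backbone"
    n_classes: int = 5
    epochs: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be classification or regression")
        if self.architecture not in ("small_cnn", "large_backbone"):
            raise ValueError("unknown architecture")


@dataclass
class EvaluationReport:
    """Test-fold metrics for one split."""

    split_id: int
    task: str
    n_train: int
    n_test: int
    accuracy: float | None = None
    confusion_matrix: np.ndarray | None = None
    classes: np.ndarray | None = None
    per_class_support: np.ndarray | None = None
    mae: float | None = None
    pearson_r: float | None = None
    predictions: np.ndarray | None = None
    true_values: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "split_id": self.split_id,
            "task": self.task,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }
        if self.accuracy is not None:
            d["accuracy"] = self.accuracy
            d["confusion_matrix"] = self.confusion_matrix.tolist()
            d["classes"] = self.classes.tolist()
            d["per_class_support"] = self.per_class_support.tolist()
        if self.mae is not None:
            d["mae"] = self.mae
            d["pearson_r"] = self.pearson_r
        return d


def crops_to_tensor(
    crops: Sequence[NucleusCrop], channels: Sequence[str], input_side: int | None = None
) -> np.ndarray:
    """Stack crop channels into a (n, H, W, C) float array scaled to [0, 1]."""
    imgs = []
    for c in crops:
        chans = [np.asarray(c.channels[name], dtype=np.float64) for name in channels]
        img = np.stack(chans, axis=-1)
        peak = 255.0 if img.max() <= 255 else 65535.0
        img = img / peak
        if input_side is not None and img.shape[:2] != (input_side, input_side):
            img = resize(img, (input_side, input_side), anti_aliasing=True, preserve_range=True)
        imgs.append(img)
    return np.asarray(imgs)


class SmallCNNClassifier(BaseEstimator, ClassifierMixin):
    """Compact 4-layer CNN classifier over (n, H, W, C) image tensors.

    Images are resampled to ``input_side`` x ``input_side`` at the model
    input. Deterministic for a fixed ``random_state`` (single-threaded
    NumPy training loop).
    """

    def __init__(
        self,
        epochs: int = 25,
        batch_size: int = 32,
        lr: float = 1e-3,
        input_side: int = 32,
        filters: tuple[int, int] = (16, 32),
        random_state: int = 0,
    ) -> None:
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.input_side = input_side
        self.filters = filters
        self.random_state = random_state

    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            X = X[..., None]
        if X.shape[1] != self.input_side or X.shape[2] != self.input_side:
            X = np.stack(
                [resize(im, (self.input_side, self.input_side), anti_aliasing=True,
                        preserve_range=True) for im in X]
            )
        return np.ascontiguousarray(X.transpose(0, 3, 1, 2), dtype=np.float32)  # NCHW

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SmallCNNClassifier":
        from .nn import SmallCNN

        Xp = self._prep(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training fold contains a single class")
        self.net_ = SmallCNN(
            in_channels=Xp.shape[1],
            input_side=self.input_side,
            n_out=len(self.classes_),
            task="classification",
            filters=self.filters,
            seed=self.random_state,
        )
        self.loss_curve_ = self.net_.fit(
            Xp, y_idx, epochs=self.epochs, batch_size=self.batch_size,
            lr=self.lr, seed=self.random_state,
        )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.net_.predict_raw(self._prep(X))
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class SmallCNNRegressor(BaseEstimator, RegressorMixin):
    """Same trunk as the classifier with a single linear output (MSE loss).

    Targets (hours) are scaled to [0, 1] internally for conditioning and
    mapped back at prediction time.
    """

    def __init__(
        self,
        epochs: int = 25,
        batch_size: int = 32,
        lr: float = 1e-3,
        input_side: int = 32,
        filters: tuple[int, int] = (16, 32),
        random_state: int = 0,
    ) -> None:
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.input_side = input_side
        self.filters = filters
        self.random_state = random_state

    _prep = SmallCNNClassifier._prep

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SmallCNNRegressor":
        from .nn import SmallCNN

        Xp = self._prep(X)
        y = np.asarray(y, dtype=np.float64)
        self.y_min_ = float(y.min())
        self.y_scale_ = float(y.max() - y.min()) or 1.0
        ys = (y - self.y_min_) / self.y_scale_
        self.net_ = SmallCNN(
            in_channels=Xp.shape[1],
            input_side=self.input_side,
            n_out=1,
            task="regression",
            filters=self.filters,
            seed=self.random_state,
        )
        self.loss_curve_ = self.net_.fit(
            Xp, ys, epochs=self.epochs, batch_size=self.batch_size,
            lr=self.lr, seed=self.random_state,
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = self.net_.predict_raw(self._prep(X)).ravel()
        return z * self.y_scale_ + self.y_min_


class HaralickRFClassifier(BaseEstimator, ClassifierMixin):
    """Random forest over offset-averaged Haralick texture features."""

    def __init__(self, n_estimators: int = 200, include_area: bool = False,
                 levels: int = 256, random_state: int = 0) -> None:
        self.n_estimators = n_estimators
        self.include_area = include_area
        self.levels = levels
        self.random_state = random_state

    def _features(self, crops) -> np.ndarray:
        table, _ = texture_feature_table(crops, levels=self.levels)
        return table if self.include_area else table[:, :-1]

    def fit(self, crops: Sequence[NucleusCrop], y: np.ndarray) -> "HaralickRFClassifier":
        self.rf_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state, n_jobs=1
        )
        self.rf_.fit(self._features(crops), y)
        self.classes_ = self.rf_.classes_
        return self

    def predict(self, crops: Sequence[NucleusCrop]) -> np.ndarray:
        return self.rf_.predict(self._features(crops))


class AreaClassifier(BaseEstimator, ClassifierMixin):
    """Nuclear-area-only baseline (random forest on the single feature)."""

    def __init__(self, n_estimators: int = 200, random_state: int = 0) -> None:
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _features(self, crops) -> np.ndarray:
        table, _ = texture_feature_table(crops)
        return table[:, -1:]

    fit = HaralickRFClassifier.fit
    predict = HaralickRFClassifier.predict


def make_large_backbone(task: str = "classification", random_state: int = 0):
    """Hook for a higher-capacity model with the small CNN's I/O contract.

    Returns an estimator consuming flattened pixels; any classifier or
    regressor with fit/predict over (n, H, W, C) tensors may be
    substituted by the caller.
    """

    class _FlattenWrap(BaseEstimator):
        def __init__(self, inner):
            self.inner = inner

        def fit(self, X, y):
            X = np.asarray(X)
            self.inner.fit(X.reshape(len(X), -1), y)
            self.classes_ = getattr(self.inner, "classes_", None)
            return self

        def predict(self, X):
            X = np.asarray(X)
            return self.inner.predict(X.reshape(len(X), -1))

    if task == "classification":
        return _FlattenWrap(MLPClassifier(hidden_layer_sizes=(128, 64), max_iter=300,
                                          random_state=random_state))
    raise ValueError("large backbone hook currently provides classification only")


def random_baseline(n_classes: int, class_counts: Sequence[int] | None = None,
                    n: int = 5000, seed: int = 0) -> dict:
    """Expected and empirical accuracy of a uniform-random classifier.

    Uniform guessing scores ``1 / n_classes`` in expectation regardless of
    the class counts; an empirical seeded run is included for comparison.
    """
    if class_counts is not None and any(c <= 0 for c in class_counts):
        raise ValueError("class counts must be positive")
    rng = np.random.default_rng(seed)
    if class_counts is None:
        labels = rng.integers(0, n_classes, size=n)
    else:
        labels = np.repeat(np.arange(n_classes), class_counts)
    guesses = rng.integers(0, n_classes, size=len(labels))
    return {
        "expected_accuracy": 1.0 / n_classes,
        "empirical_accuracy": float(np.mean(guesses == labels)),
        "n": int(len(labels)),
    }


# ---------------------------------------------------------------------------
# Split-based training / evaluation
# ---------------------------------------------------------------------------


def _assert_no_leakage(crops, split: FoldSplit) -> None:
    train_f = {crops[i].field_id for i in split.train_idx}
    test_f = {crops[i].field_id for i in split.test_idx}
    if train_f & test_f:
        raise AssertionError(f"field leakage in split {split.split_id}: {train_f & test_f}")


def _confusion(y_true, y_pred, classes):
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def evaluate_on_split(
    model,
    crops: Sequence[NucleusCrop],
    split: FoldSplit,
    spec: ModelSpec,
    augment: bool = True,
) -> EvaluationReport:
    """Train on the split's train fold and score its test fold.

    Training uses right-angle augmented copies of the train crops (each
    copy stays in its source's fold by construction); test metrics are
    computed on the unaugmented originals. Image models get tensors of
    ``spec.input_channels``; feature models (Haralick/area) get the crops
    directly.
    """
    _assert_no_leakage(crops, split)
    train_crops = [crops[i] for i in split.train_idx]
    test_crops = [crops[i] for i in split.test_idx]
    if augment:
        train_aug = [a.crop for c in train_crops for a in augment_rotations(c)]
    else:
        train_aug = list(train_crops)
    y_train = np.array([c.timepoint_h for c in train_aug])
    y_test = np.array([c.timepoint_h for c in test_crops])
    if spec.task == "classification" and len(np.unique(y_train)) < spec.n_classes:
        raise ValueError("a class is absent from the training fold")

    feature_model = isinstance(model, (HaralickRFClassifier, AreaClassifier))
    if feature_model:
        model.fit(train_aug, y_train)
        y_pred = model.predict(test_crops)
    else:
        side = getattr(model, "input_side", 32)
        Xtr = crops_to_tensor(train_aug, spec.input_channels, input_side=side)
        Xte = crops_to_tensor(test_crops, spec.input_channels, input_side=side)
        model.fit(Xtr, y_train)
        y_pred = model.predict(Xte)

    if spec.task == "classification":
        classes = np.unique(np.concatenate([y_train, y_test]))
        cm = _confusion(y_test, y_pred, classes)
        return EvaluationReport(
            split_id=split.split_id,
            task="classification",
            n_train=len(train_aug),
            n_test=len(test_crops),
            accuracy=float(np.mean(y_pred == y_test)),
            confusion_matrix=cm,
            classes=classes,
            per_class_support=cm.sum(axis=1),
            predictions=np.asarray(y_pred),
            true_values=y_test,
        )
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_test) > 1 and np.std(y_pred) > 0 and np.std(y_test) > 0:
        r = float(stats.pearsonr(y_pred, y_test)[0])
    else:
        r = float("nan")
    return EvaluationReport(
        split_id=split.split_id,
        task="regression",
        n_train=len(train_aug),
        n_test=len(test_crops),
        mae=float(np.mean(np.abs(y_pred - y_test))),
        pearson_r=r,
        predictions=y_pred,
        true_values=y_test,
    )


def shuffled_label_accuracy(
    crops: Sequence[NucleusCrop],
    split: FoldSplit,
    spec: ModelSpec,
    input_side: int = 32,
    seed: int = 0,
) -> float:
    """Permutation-null control: train with shuffled labels, score everything.

    Train-fold labels are permuted at the source-crop level (augmented
    copies inherit their source's shuffled label); the trained model is
    then scored against the true labels of all unaugmented crops. Under
    the null the expected accuracy is 1/n_classes.
    """
    _assert_no_leakage(crops, split)
    rng = np.random.default_rng(seed)
    train_crops = [crops[i] for i in split.train_idx]
    perm = rng.permutation(len(train_crops))
    shuffled = {c.crop_id: train_crops[j].timepoint_h for c, j in zip(train_crops, perm)}
    train_aug = [a for c in train_crops for a in augment_rotations(c)]
    y_train = np.array([shuffled[a.source_crop_id] for a in train_aug])
    model = build_model(spec, input_side=input_side)
    Xtr = crops_to_tensor([a.crop for a in train_aug], spec.input_channels, input_side=input_side)
    model.fit(Xtr, y_train)
    Xall = crops_to_tensor(crops, spec.input_channels, input_side=input_side)
    y_true = np.array([c.timepoint_h for c in crops])
    return float(np.mean(model.predict(Xall) == y_true))


def summarize_reports(reports: Sequence[EvaluationReport]) -> dict:
    """Mean and sd over splits, mirroring averages over repeated divisions."""
    out: dict = {"n_splits": len(reports)}
    accs = [r.accuracy for r in reports if r.accuracy is not None]
    if accs:
        out["accuracy_mean"] = float(np.mean(accs))
        out["accuracy_sd"] = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
    maes = [r.mae for r in reports if r.mae is not None]
    if maes:
        out["mae_mean"] = float(np.mean(maes))
        out["mae_sd"] = float(np.std(maes, ddof=1)) if len(maes) > 1 else 0.0
        rs = [r.pearson_r for r in reports]
        out["pearson_r_mean"] = float(np.mean(rs))
    return out


def build_model(spec: ModelSpec, input_side: int = 32):
    """Instantiate the estimator named by a ModelSpec."""
    if spec.architecture == "large_backbone":
        return make_large_backbone(spec.task, random_state=spec.seed)
    if spec.task == "classification":
        return SmallCNNClassifier(epochs=spec.epochs, input_side=input_side,
                                  random_state=spec.seed)
    return SmallCNNRegressor(epochs=spec.epochs, input_side=input_side,
                             random_state=spec.seed)


def train_classifier(spec: ModelSpec, crops, split: FoldSplit, input_side: int = 32):
    """Train the spec'd classifier on one split; returns (model, report)."""
    if spec.task != "classification":
        raise ValueError("spec.task must be classification")
    model = build_model(spec, input_side=input_side)
    return model, evaluate_on_split(model, crops, split, spec)


def train_regressor(spec: ModelSpec, crops, split: FoldSplit, input_side: int = 32):
    """Train the spec'd regressor on one split; returns (model, report)."""
    if spec.task != "regression":
        raise ValueError("spec.task must be regression")
    model = build_model(spec, input_side=input_side)
    return model, evaluate_on_split(model, crops, split, spec)


def train_rf_baseline(crops, split: FoldSplit, include_area: bool = False, seed: int = 0):
    """Haralick random-forest baseline on one split; returns (model, report)."""
    spec = ModelSpec(task="classification", input_channels=("nucleus",), seed=seed)
    model = HaralickRFClassifier(include_area=include_area, random_state=seed)
    return model, evaluate_on_split(model, crops, split, spec)


def train_area_baseline(crops, split: FoldSplit, seed: int = 0):
    """Nuclear-area-only baseline on one split; returns (model, report)."""
    spec = ModelSpec(task="classification", input_channels=("nucleus",), seed=seed)
    model = AreaClassifier(random_state=seed)
    return model, evaluate_on_split(model, crops, split, spec)
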