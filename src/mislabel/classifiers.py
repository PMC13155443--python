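"""Base learners: tiny trainable CNNs, a frozen-backbone + new-head recipe,
and an oracle test double — all scikit-learn style estimators.

The ensemble contract is deliberately small: an estimator is anything with
``fit(X, y)`` and ``predict_proba(X)`` where X is a (N, H, W, 3) float image
array and the returned rows are softmax vectors over the class vocabulary.

``TinyCNNClassifier`` is a small conv stack whose single dense-layer width
is the "variant" knob, giving a cheap near-homogeneous ensemble family.
``BackboneHeadClassifier`` follows the transfer-learning head-replacement
recipe: a frozen feature extractor, then three new fully connected layers
of decreasing width ending in K softmax units (ReLU in between); only the
head is trained. Any object with a ``transform(X) -> features`` method can
serve as the backbone; the default is a fixed, seeded random convolutional
extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from ._nn import Conv2D, Dense, Flatten, MeanPool2, Network, ReLU, sgd_fit, softmax
from .datamodel import ClassVocabulary, ImageDataset

__all__ = [
    "TrainConfig",
    "ClassifierSpec",
    "TinyCNNClassifier",
    "RandomConvFeatures",
    "BackboneHeadClassifier",
    "OracleClassifier",
    "build_classifier",
    "train",
    "predict_proba",
    "predict_label",
    "softmax",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings. Defaults follow the fine-tuning recipe
    (30 epochs, fixed learning rate 0.001, batch 32, plain SGD)."""

    epochs: int = 30
    learning_rate: float = 0.001
    batch_size: int = 32
    seed: int = 0
    momentum: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class ClassifierSpec:
    """Declarative recipe for one ensemble member.

    family 'tiny_cnn': variant is the dense-layer width (int).
    family 'finetune_backbone': variant names the backbone ('random_conv').
    """

    family: str
    variant: int | str
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("tiny_cnn", "finetune_backbone"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.family == "tiny_cnn" and int(self.variant) < 1:
            raise ValueError("tiny_cnn variant (dense width) must be >= 1")
        if self.family == "finetune_backbone" and self.variant != "random_conv":
            raise ValueError(f"unknown backbone variant {self.variant!r}")


def _check_images(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError(f"expected images of shape (N, H, W, 3), got {X.shape}")
    return X


class _NumpyNetClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery for the numpy-net estimators."""

    # subclasses define _build(input_shape, n_out, rng) -> Network
    # and _features(X) -> array fed to the network

    def fit(self, X, y):
        X = _check_images(X)
        y = np.asarray(y, dtype=np.int64)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty dataset")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if self.classes is not None:
            self.classes_ = np.asarray(self.classes, dtype=np.int64)
        else:
            self.classes_ = np.unique(y)
        if np.setdiff1d(y, self.classes_).size:
            raise ValueError("y contains labels outside the declared classes")
        y_idx = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.random_state)
        feats = self._features(X)
        self.net_ = self._build(feats.shape[1:], len(self.classes_), rng)
        self.loss_curve_ = sgd_fit(
            self.net_,
            feats,
            y_idx,
            len(self.classes_),
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            rng=rng,
            momentum=self.momentum,
        )
        self.input_shape_ = X.shape[1:]
        return self

    def predict_proba(self, X):
        X = _check_images(X)
        if X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"input shape {X.shape[1:]} != training shape {self.input_shape_}"
            )
        return self.net_.predict_proba(self._features(X))

    def predict(self, X):
        # argmax resolves ties toward the lowest class index
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    @property
    def n_parameters_(self) -> int:
        return self.net_.n_parameters()

    def _features(self, X: np.ndarray) -> np.ndarray:
        return X


class TinyCNNClassifier(_NumpyNetClassifier):
    """Small conv stack + one dense layer (the variant) + K-way softmax.

    Two 3x3 conv/ReLU/mean-pool stages feed a single hidden dense layer of
    ``dense_width`` units, then the K-unit output layer. Initialization and
    batch order are deterministic from ``random_state``.
    """

    def __init__(
        self,
        dense_width: int = 64,
        conv_channels: tuple[int, int] = (8, 16),
        epochs: int = 30,
        learning_rate: float = 0.001,
        momentum: float = 0.0,
        batch_size: int = 32,
        random_state: int | None = None,
        classes=None,
    ):
        self.dense_width = dense_width
        self.conv_channels = conv_channels
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.random_state = random_state
        self.classes = classes

    def _build(self, input_shape, n_out, rng):
        H, W, C = input_shape
        c1, c2 = self.conv_channels
        h = (H - 2) // 2  # after conv1 (valid 3x3) + pool
        w = (W - 2) // 2
        h = (h - 2) // 2  # after conv2 + pool
        w = (w - 2) // 2
        if h < 1 or w < 1:
            raise ValueError(f"input {input_shape} too small for the conv stack")
        return Network(
            [
                Conv2D(C, c1, 3, rng),
                ReLU(),
                MeanPool2(),
                Conv2D(c1, c2, 3, rng),
                ReLU(),
                MeanPool2(),
                Flatten(),
                Dense(h * w * c2, int(self.dense_width), rng),
                ReLU(),
                Dense(int(self.dense_width), n_out, rng, scale=1.0),
            ]
        )


class RandomConvFeatures:
    """Frozen feature extractor: a fixed seeded random conv stack.

    Stands in for a pretrained convolutional trunk where no pretrained
    weights are available: random convolutions followed by ReLU and pooling
    are a classic cheap feature map. Synthetic by construction — it carries
    no learned knowledge.
    """

    def __init__(self, channels: tuple[int, int] = (8, 16), seed: int = 0):
        self.channels = channels
        self.seed = seed
        self._net: Network | None = None

    def _ensure(self, input_shape):
        if self._net is None:
            rng = np.random.default_rng(self.seed)
            c1, c2 = self.channels
            self._net = Network(
                [
                    Conv2D(input_shape[-1], c1, 3, rng),
                    ReLU(),
                    MeanPool2(),
                    Conv2D(c1, c2, 3, rng),
                    ReLU(),
                    MeanPool2(),
                    Flatten(),
                ]
            )

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = _check_images(X)
        self._ensure(X.shape[1:])
        out = [
            self._net.forward(X[i : i + 256].astype(np.float32))
            for i in range(0, len(X), 256)
        ]
        return np.concatenate(out, axis=0)


class BackboneHeadClassifier(_NumpyNetClassifier):
    """Frozen backbone + three new fully connected layers of decreasing
    width ending in K softmax units (ReLU between); only the head trains."""

    def __init__(
        self,
        backbone=None,
        head_widths: tuple[int, int] = (256, 64),
        epochs: int = 30,
        learning_rate: float = 0.001,
        momentum: float = 0.0,
        batch_size: int = 32,
        random_state: int | None = None,
        classes=None,
    ):
        self.backbone = backbone
        self.head_widths = head_widths
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.random_state = random_state
        self.classes = classes

    def _features(self, X):
        if not hasattr(self, "backbone_"):
            self.backbone_ = (
                self.backbone
                if self.backbone is not None
                else RandomConvFeatures(seed=0 if self.random_state is None else self.random_state)
            )
        return self.backbone_.transform(X).astype(np.float32)

    def _build(self, input_shape, n_out, rng):
        w1, w2 = self.head_widths
        if not w1 >= w2:
            raise ValueError("head widths must be decreasing")
        (n_feat,) = input_shape
        return Network(
            [
                Dense(n_feat, int(w1), rng),
                ReLU(),
                Dense(int(w1), int(w2), rng),
                ReLU(),
                Dense(int(w2), n_out, rng, scale=1.0),
            ]
        )


class OracleClassifier(BaseEstimator, ClassifierMixin):
    """Test double that 'predicts' each sample's hidden true label with a
    fixed confidence, identifying samples by their image bytes.

    Satisfies the ensemble estimator contract (fit is a no-op, predict_proba
    rows are valid softmax vectors) so vote logic can be exercised with the
    learning step removed.
    """

    def __init__(self, lookup: dict, n_classes: int, confidence: float = 1.0):
        self.lookup = lookup
        self.n_classes = n_classes
        self.confidence = confidence

    @classmethod
    def from_dataset(cls, dataset: ImageDataset, confidence: float = 1.0):
        if dataset.true is None:
            raise ValueError("oracle needs a dataset with true labels")
        lookup = {
            dataset.images[i].tobytes(): int(dataset.true[i])
            for i in range(len(dataset))
        }
        if len(lookup) != len(dataset):
            raise ValueError("oracle requires distinct image contents")
        return cls(lookup, dataset.vocabulary.K, confidence)

    def fit(self, X, y):
        self.classes_ = np.arange(self.n_classes)
        return self

    def predict_proba(self, X):
        X = _check_images(X)
        K = self.n_classes
        rest = (1.0 - self.confidence) / (K - 1)
        out = np.full((len(X), K), rest, dtype=np.float64)
        for i in range(len(X)):
            out[i, self.lookup[X[i].tobytes()]] = self.confidence
        return out

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)


def build_classifier(
    spec: ClassifierSpec,
    vocabulary: ClassVocabulary,
    input_shape: tuple[int, int, int] | None = None,
) -> BaseEstimator:
    """Instantiate an untrained estimator from a declarative spec."""
    if input_shape is not None and (len(input_shape) != 3 or input_shape[2] != 3):
        raise ValueError("input_shape must be (H, W, 3)")
    classes = np.arange(vocabulary.K)
    if spec.family == "tiny_cnn":
        return TinyCNNClassifier(
            dense_width=int(spec.variant),
            random_state=spec.init_seed,
            classes=classes,
        )
    return BackboneHeadClassifier(random_state=spec.init_seed, classes=classes)


def train(classifier, dataset: ImageDataset, config: TrainConfig):
    """Fit a fresh clone of ``classifier`` on the dataset's assigned labels."""
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    fitted = clone(classifier)
    params = fitted.get_params()
    for key, value in (
        ("epochs", config.epochs),
        ("learning_rate", config.learning_rate),
        ("batch_size", config.batch_size),
        ("momentum", config.momentum),
    ):
        if key in params:
            fitted.set_params(**{key: value})
    return fitted.fit(dataset.images, dataset.assigned)


def predict_proba(trained, images: np.ndarray) -> np.ndarray:
    """Per-image class-probability vectors (rows sum to 1)."""
    return trained.predict_proba(_check_images(images))


def predict_label(
    proba: np.ndarray, vocabulary: ClassVocabulary
) -> tuple[int, float]:
    """argmax decision with its probability; ties go to the lowest index."""
    proba = np.asarray(proba, dtype=np.float64)
    if proba.shape != (vocabulary.K,):
        raise ValueError(f"probability vector must have length {vocabulary.K}")
    idx = int(np.argmax(proba))
    return idx, float(proba[idx])
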