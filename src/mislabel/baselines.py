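"""Classical comparators: pixel/PCA features, KNN, and k-means.

These reproduce the standard non-deep baselines one would try before an
ensemble of CNNs: nearest-neighbour classification on (possibly
PCA-reduced) pixel vectors, and k-means clustering scored by mapping each
cluster to its majority true class.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .datamodel import ImageDataset

__all__ = ["extract_features", "knn_evaluate", "kmeans_evaluate"]


def extract_features(
    dataset: ImageDataset, mode: str = "pixels", n_components: int = 2
) -> np.ndarray:
    """Row-per-sample feature matrix: flattened pixels or a PCA projection."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    pixels = dataset.images.reshape(len(dataset), -1).astype(np.float64)
    if mode == "pixels":
        return pixels
    if mode == "pca":
        if n_components > min(pixels.shape):
            raise ValueError(
                f"n_components={n_components} exceeds min(N, pixel count)"
            )
        return PCA(n_components=n_components, random_state=0).fit_transform(pixels)
    raise ValueError(f"unknown feature mode {mode!r}")


def knn_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Seeded split, k-nearest-neighbour (Euclidean) classification.

    Returns (confusion matrix with rows = true classes, accuracy).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = np.asarray(labels)
    X_tr, X_te, y_tr, y_te = train_test_split(
        features, labels, test_size=test_fraction, random_state=seed
    )
    if k > len(X_tr):
        raise ValueError(f"k={k} exceeds training size {len(X_tr)}")
    clf = KNeighborsClassifier(n_neighbors=k, metric="euclidean").fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    cm = confusion_matrix(y_te, pred, labels=np.unique(labels))
    return cm, float((pred == y_te).mean())


def kmeans_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    k_clusters: int,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """k-means with majority-mapped accuracy.

    Each cluster is mapped to the majority true class among its members;
    accuracy is computed under that mapping, so it is always at least the
    overall majority-class fraction. Returns (confusion matrix with rows =
    true classes and columns = mapped classes, mapped accuracy).
    """
    labels = np.asarray(labels)
    if k_clusters < 1:
        raise ValueError("k_clusters must be >= 1")
    if k_clusters > len(features):
        raise ValueError("k_clusters exceeds number of samples")
    km = KMeans(n_clusters=k_clusters, random_state=seed, n_init=10).fit(features)
    assign = km.labels_
    classes = np.unique(labels)
    mapped = np.empty_like(labels)
    for c in range(k_clusters):
        members = labels[assign == c]
        if len(members) == 0:
            majority = classes[0]
        else:
            vals, counts = np.unique(members, return_counts=True)
            majority = vals[np.argmax(counts)]
        mapped[assign == c] = majority
    cm = confusion_matrix(labels, mapped, labels=classes)
    return cm, float((mapped == labels).mean())
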