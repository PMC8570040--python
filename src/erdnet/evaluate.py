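"""Accuracy, paired significance testing, and deep-feature geometry.

The discriminative-power claim of center-loss training is made measurable
here: features are projected to 2-D by PCA for display, while the
quantitative comparison uses :func:`class_dispersion` on the raw penultimate
features — mean within-class squared distance to the class centroid
(intra-class variance) against mean pairwise centroid distance (inter-class
separation).  PCA is display-only because projection discards variance and
would bias the dispersion comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "DispersionSummary",
    "accuracy",
    "paired_ttest",
    "pca_project",
    "class_dispersion",
    "plot_learning_curves",
    "plot_feature_scatter",
]


@dataclass(frozen=True)
class DispersionSummary:
    """Within-class spread vs between-class separation of a feature cloud."""

    intra_class_variance: float  # mean over classes of mean squared distance to centroid
    inter_center_distance: float  # mean pairwise Euclidean distance between centroids


def accuracy(predicted_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Percent agreement: 100 * matches / n."""
    predicted_labels = np.asarray(predicted_labels)
    true_labels = np.asarray(true_labels)
    if predicted_labels.shape != true_labels.shape:
        raise ValueError(
            f"length mismatch: {predicted_labels.shape} vs {true_labels.shape}"
        )
    if predicted_labels.size == 0:
        raise ValueError("cannot compute accuracy of empty label vectors")
    return 100.0 * float(np.mean(predicted_labels == true_labels))


def paired_ttest(acc_a: np.ndarray, acc_b: np.ndarray) -> tuple[float, float]:
    """Classical paired t-test on per-subject accuracy vectors.

    t = mean(d) / (sd(d) / sqrt(n)) on the differences d = a - b with n - 1
    degrees of freedom; returns (t, two-sided p).
    """
    from scipy.stats import t as t_dist

    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("all paired differences are identical (zero variance)")
    t_stat = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * t_dist.sf(abs(t_stat), df=n - 1))
    return t_stat, p


def pca_project(features: np.ndarray, k: int = 2) -> np.ndarray:
    """Project features onto the top-k principal axes (covariance PCA).

    Features are mean-centered but not standardized.  Component signs are
    fixed so each axis's largest-magnitude loading is positive, making the
    projection deterministic.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n, d = features.shape
    if n < k or d < k:
        raise ValueError(f"need at least k={k} samples and dimensions; got {features.shape}")
    pca = PCA(n_components=k, svd_solver="full")
    projected = pca.fit_transform(features)
    comps = pca.components_
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            projected[:, i] = -projected[:, i]
    return projected


def class_dispersion(
    features: np.ndarray, labels: np.ndarray, n_classes: int | None = None
) -> DispersionSummary:
    """Intra-class variance and mean inter-centroid distance of a labeled cloud.

    With ``n_classes`` given, every class in ``[0, n_classes)`` must have at
    least one member; otherwise the classes present in ``labels`` are used.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if n_classes is not None:
        classes = np.arange(n_classes)
        missing = set(classes) - set(np.unique(labels))
        if missing:
            raise ValueError(f"class(es) {sorted(missing)} have no members")
    else:
        classes = np.unique(labels)
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels disagree in length")
    centroids = {}
    intra = []
    for j in classes:
        members = features[labels == j]
        if members.shape[0] == 0:
            raise ValueError(f"class {j} has no members")
        centroid = members.mean(axis=0)
        centroids[j] = centroid
        intra.append(float(((members - centroid) ** 2).sum(axis=1).mean()))
    if len(classes) >= 2:
        inter = float(
            np.mean(
                [
                    np.linalg.norm(centroids[a] - centroids[b])
                    for a, b in combinations(classes, 2)
                ]
            )
        )
    else:
        inter = 0.0
    return DispersionSummary(
        intra_class_variance=float(np.mean(intra)),
        inter_center_distance=inter,
    )


# ---------------------------------------------------------------------------
# plots (display helpers; all quantitative claims go through the functions above)
# ---------------------------------------------------------------------------

def plot_learning_curves(history, path=None, ax=None):
    """Train/test combined-loss curves over epochs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    epochs = history["epoch"]
    ax.plot(epochs, history["train_loss"], label="train loss")
    ax.plot(epochs, history["test_loss"], label="test loss")
    ax.set_xlabel("epoch")
    ax.set_ylabel("combined loss")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_feature_scatter(features, labels, path=None, ax=None):
    """2-D PCA scatter of deep features colored by class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    projected = pca_project(features, k=2)
    labels = np.asarray(labels)
    for j in np.unique(labels):
        pts = projected[labels == j]
        ax.scatter(pts[:, 0], pts[:, 1], s=8, label=f"class {j}")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
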