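"""Per-group feature extraction (PCA) and HDBSCAN clustering.

Each electrode group is clustered independently in its own 2-component PCA
space: the first two principal components carry essentially all of the
waveform variance that sits above the noise floor, and a 2-D space keeps
the density estimates that HDBSCAN relies on well conditioned.

HDBSCAN is chosen over centroid- or Gaussian-mixture-style methods for two
reasons: spike clouds are routinely non-Gaussian, and temporally
overlapping spikes (collisions) produce distorted waveforms that land in
low-density regions of the feature space — HDBSCAN labels these ``-1``
(outliers) instead of corrupting the clusters, and the matching stage
later recovers the spikes hidden inside them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA

from .group import SnippetGroup
from .waveforms import align_peak_matrix

__all__ = [
    "FeatureSpace",
    "ClusterLabeling",
    "fit_features",
    "cluster_group",
    "cluster_all",
]


@dataclass
class FeatureSpace:
    """A group's PCA basis and the snippets projected into it."""

    components: np.ndarray                # (n_components, n_samples)
    projected: np.ndarray                 # (n_snippets, n_components)
    explained_variance_ratio: np.ndarray  # (n_components,)
    mean: np.ndarray                      # (n_samples,)


@dataclass
class ClusterLabeling:
    """Per-snippet labels; ``-1`` marks outliers, clusters are 0..n_clusters-1."""

    labels: np.ndarray
    n_clusters: int


def fit_features(group: SnippetGroup, n_components: int = 2,
                 feature_slice: slice | None = None,
                 align_at: float | None = None) -> FeatureSpace:
    """Fit a per-group PCA and project every snippet.

    ``align_at`` re-anchors every waveform on its interpolated absolute
    peak before anything else: discrete peak alignment can split one
    unit's spikes into phase cohorts one sample apart, which a
    sample-by-sample feature space would then resolve into two clusters.
    ``feature_slice`` restricts the PCA input to a sub-window of each
    waveform (the snippet window is deliberately longer than a spike, so
    its flanks can carry tails of *neighboring* spikes; clustering on a
    spike-width centre window keeps that contamination out of the feature
    space).  If the group holds fewer snippets than ``n_components`` the
    basis is truncated to what the data supports (the caller decides
    whether such a degenerate group is worth clustering at all).
    """
    X = group.waveform_matrix()
    if align_at is not None:
        X = align_peak_matrix(X, align_at)
    if feature_slice is not None:
        X = X[:, feature_slice]
    n_comp = min(n_components, X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    projected = pca.fit_transform(X)
    return FeatureSpace(
        components=pca.components_,
        projected=projected,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
    )


def cluster_group(
    features: FeatureSpace,
    min_cluster_size: int = 10,
    min_samples: int = 5,
) -> ClusterLabeling:
    """Hierarchical density clustering with outlier marking.

    Clustering runs on the mutual-reachability transform of the projected
    points (``d_mreach(a,b) = max{core(a), core(b), d(a,b)}``), extracting
    the stable clusters of the condensed tree; low-density points come
    back labeled ``-1``.  Groups too small to contain any cluster of
    ``min_cluster_size`` are labeled all-outlier and left to the matching
    stage rather than forming an unreliable template.

    Labels are relabeled to 0..n_clusters-1 in order of each cluster's
    first appearance, so output is stable under point order.
    """
    X = features.projected
    n = X.shape[0]
    if n < min_cluster_size:
        return ClusterLabeling(labels=np.full(n, -1, dtype=int), n_clusters=0)
    model = HDBSCAN(
        min_cluster_size=min_cluster_size,
        min_samples=min_samples,
        allow_single_cluster=True,
        copy=True,
    )
    raw = model.fit_predict(X)
    labels = np.full(n, -1, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab < 0:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        labels[i] = mapping[lab]
    return ClusterLabeling(labels=labels, n_clusters=len(mapping))


def cluster_all(
    groups: list[SnippetGroup],
    n_components: int = 2,
    min_cluster_size: int = 10,
    min_samples: int = 5,
    feature_slice: slice | None = None,
    align_at: float | None = None,
) -> list[tuple[SnippetGroup, FeatureSpace, ClusterLabeling]]:
    """Cluster every group independently (parallel-safe by construction)."""
    out = []
    for grp in groups:
        feats = fit_features(grp, n_components=n_components,
                             feature_slice=feature_slice, align_at=align_at)
        labeling = cluster_group(feats, min_cluster_size, min_samples)
        out.append((grp, feats, labeling))
    return out


def plot_features(features: FeatureSpace, labeling: ClusterLabeling, ax=None):
    """Diagnostic 2-D scatter of a group's feature space, colored by label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    X = features.projected
    out = labeling.labels < 0
    ax.scatter(X[out, 0], X[out, 1], c="k", s=8, marker="x", label="outlier")
    for lab in range(labeling.n_clusters):
        m = labeling.labels == lab
        ax.scatter(X[m, 0], X[m, 1], s=8, label=f"cluster {lab}")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize="small")
    return ax
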