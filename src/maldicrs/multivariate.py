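"""Multivariate response analysis: PCA, sparse PCA and curve-shape clustering.

PCA on the feature-standardized intensity matrix visualizes the global
dose response across spots; sparse PCA (L1-penalized loadings) reduces the
feature space to a small selected subset, which can reveal coordinated
responses that no single curve shows convincingly.  Curve-shape clustering
groups fitted dose-response curves that share a sigmoidal shape — evaluated
on a common log-dose grid and min–max scaled so the grouping is free of
intensity scale and offset — which helps find weaker features following the
same (or the reverse) trend as a strong responder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA, SparsePCA
from sklearn.metrics import silhouette_score

from .curves import CurveFit
from .preprocess import IntensityMatrix

__all__ = [
    "PCAResult",
    "SparsePCAResult",
    "pca_global",
    "sparse_pca",
    "cluster_curve_shapes",
    "curve_shape_grid",
]


@dataclass
class PCAResult:
    scores: np.ndarray            # spots × components
    loadings: np.ndarray          # components × retained features
    explained_variance_ratio: np.ndarray
    feature_indices: np.ndarray   # indices of retained (nonzero-variance) features
    spots: list[str]


@dataclass
class SparsePCAResult:
    scores: np.ndarray
    loadings: np.ndarray          # components × retained features, with exact zeros
    selected: np.ndarray          # feature indices with any nonzero loading
    feature_indices: np.ndarray
    spots: list[str]


def _standardized(m: IntensityMatrix) -> tuple[np.ndarray, np.ndarray]:
    x = m.values.T  # spots × features
    sd = x.std(axis=0, ddof=0)
    keep = np.flatnonzero(sd > 0)
    if len(keep) < len(sd):
        warnings.warn(f"dropping {len(sd) - len(keep)} zero-variance features")
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    return x, keep


def pca_global(m: IntensityMatrix, n_components: int = 2) -> PCAResult:
    """PCA of the feature-standardized intensity matrix (spots as samples).

    Zero-variance features are dropped (with a warning) before
    standardization.  Explained-variance ratios sum to ≤ 1.
    """
    if len(m.spots) < 2:
        raise ValueError("PCA requires at least 2 spots")
    x, keep = _standardized(m)
    if n_components > min(x.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_spots, n_features)={min(x.shape)}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    return PCAResult(
        scores=scores,
        loadings=model.components_,
        explained_variance_ratio=model.explained_variance_ratio_,
        feature_indices=keep,
        spots=list(m.spots),
    )


def sparse_pca(
    m: IntensityMatrix,
    n_components: int = 2,
    l1_penalty: float = 1.0,
    random_state: int = 0,
) -> SparsePCAResult:
    """Sparse PCA with an L1 penalty on the loadings.

    Loadings contain exact zeros; the *selected set* is the features with any
    nonzero loading on any component.  The selected-set size is
    non-increasing along an increasing penalty ladder (up to algorithmic
    ties).  ``l1_penalty = 0`` reduces to an unpenalized fit whose support is
    all retained features.
    """
    if l1_penalty < 0:
        raise ValueError("l1_penalty must be >= 0")
    x, keep = _standardized(m)
    n_components = min(n_components, min(x.shape))
    if l1_penalty == 0:
        model = PCA(n_components=n_components, svd_solver="full")
        scores = model.fit_transform(x)
        loadings = model.components_
    else:
        model = SparsePCA(
            n_components=n_components,
            alpha=l1_penalty,
            ridge_alpha=0.01,
            method="lars",
            random_state=random_state,
            max_iter=2000,
        )
        scores = model.fit_transform(x)
        loadings = model.components_
    selected_local = np.flatnonzero(np.any(loadings != 0, axis=0))
    return SparsePCAResult(
        scores=scores,
        loadings=loadings,
        selected=keep[selected_local],
        feature_indices=keep,
        spots=list(m.spots),
    )


def curve_shape_grid(fits: list[CurveFit], n_grid: int = 50) -> np.ndarray:
    """Evaluate fitted curves on a shared log-dose grid, min–max scaled.

    Each row is one curve rescaled to [0, 1] over the grid, making the
    representation invariant to per-feature affine intensity changes; a flat
    curve (range ~ 0) maps to the constant 0.5 profile.
    """
    conc_min = min(f.conc_min for f in fits)
    conc_max = max(f.conc_max for f in fits)
    grid = np.exp(np.linspace(np.log(conc_min), np.log(conc_max), n_grid))
    shapes = np.empty((len(fits), n_grid))
    for i, f in enumerate(fits):
        y = f.predict(grid)
        span = y.max() - y.min()
        scale = max(abs(y).max(), 1e-300)
        if span <= 1e-9 * scale:
            shapes[i] = 0.5
        else:
            shapes[i] = (y - y.min()) / span
    return shapes


def cluster_curve_shapes(
    fits: list[CurveFit],
    k: int | str = "auto",
    n_grid: int = 50,
    random_state: int = 0,
) -> np.ndarray:
    """k-means clustering of fitted response-curve shapes.

    ``k="auto"`` selects k ∈ [2, 6] by silhouette score.  Curves with the
    same shape co-cluster regardless of intensity scale; mirrored (reverse
    response) curves land in distinct clusters.  If every curve is flat a
    single cluster 0 is returned with a warning.
    """
    converged = [f for f in fits if f.converged]
    if len(converged) < 2:
        raise ValueError("need at least 2 converged fits to cluster")
    shapes = curve_shape_grid(converged, n_grid=n_grid)

    if np.allclose(shapes, 0.5):
        warnings.warn("all response curves are flat; single shape cluster")
        labels_conv = np.zeros(len(converged), dtype=int)
    elif isinstance(k, str) and k == "auto":
        best_labels, best_score = None, -np.inf
        distinct = len(np.unique(shapes.round(9), axis=0))
        for kk in range(2, min(6, len(converged) - 1, distinct) + 1):
            km = KMeans(n_clusters=kk, n_init=10, random_state=random_state)
            lab = km.fit_predict(shapes)
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(shapes, lab)
            if score > best_score:
                best_labels, best_score = lab, score
        if best_labels is None:
            best_labels = np.zeros(len(converged), dtype=int)
        labels_conv = best_labels
    else:
        km = KMeans(n_clusters=int(k), n_init=10, random_state=random_state)
        labels_conv = km.fit_predict(shapes)

    labels = np.full(len(fits), -1, dtype=int)
    j = 0
    for i, f in enumerate(fits):
        if f.converged:
            labels[i] = labels_conv[j]
            j += 1
    return labels
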