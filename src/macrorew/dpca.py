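"""Dihedral principal component analysis (dPCA) and PC-space clustering.

Torsion angles are circular, so each angle θ is encoded as the pair
(sin θ, cos θ) before PCA; this avoids the ±180° wrap artifact. PCA is an
eigendecomposition of the (optionally weighted) covariance of the encoded
features, with a deterministic sign convention. Conformational states are
found by K-means on the leading PCs, reported sorted by population, and
each cluster is summarised by the member frame closest to its centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "PCAModel",
    "ClusterResult",
    "encode_circular",
    "fit_pca",
    "project",
    "kmeans_cluster",
    "representative_frames",
    "match_external_representative",
]


@dataclass
class PCAModel:
    """Fitted PCA: feature mean, orthonormal components (rows), eigenvalues
    sorted descending. Eigenvalues are variances along the components and
    sum to the total feature variance."""

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


@dataclass
class ClusterResult:
    """K-means outcome: per-frame labels (clusters ordered by descending
    population), centroids, and per-cluster representative frame indices
    (−1 for an empty cluster)."""

    labels: np.ndarray
    centroids: np.ndarray
    representative_frames: np.ndarray

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def populations(self, weights: np.ndarray | None = None) -> np.ndarray:
        if weights is None:
            weights = np.full(len(self.labels), 1.0 / len(self.labels))
        return np.array([weights[self.labels == c].sum() for c in range(self.k)])


def encode_circular(angles_deg: np.ndarray) -> np.ndarray:
    """Encode frames × T torsion angles (degrees) as frames × 2T features
    ordered (sin θ1, cos θ1, sin θ2, cos θ2, ...)."""
    angles = np.asarray(angles_deg, dtype=float)
    if not np.isfinite(angles).all():
        raise ValueError("angles must be finite")
    rad = np.radians(angles)
    n_frames, n_tor = rad.shape
    feats = np.empty((n_frames, 2 * n_tor))
    feats[:, 0::2] = np.sin(rad)
    feats[:, 1::2] = np.cos(rad)
    return feats


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make each component's largest-magnitude entry positive (first on tie)."""
    out = components.copy()
    for i, row in enumerate(out):
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            out[i] = -row
    return out


def fit_pca(features: np.ndarray, weights: np.ndarray | None = None) -> PCAModel:
    """Eigendecomposition of the (weighted) covariance of mean-centered features.

    The covariance uses the total-weight denominator (population form), so
    the eigenvalue sum equals the total feature variance under the same
    convention. Uniform weights reproduce the unweighted fit exactly.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D feature matrix with >= 2 frames")
    if weights is None:
        w = np.full(X.shape[0], 1.0 / X.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != X.shape[0]:
            raise ValueError("weights length must match frame count")
        w = w / w.sum()
    mean = w @ X
    Xc = X - mean
    cov = (Xc * w[:, None]).T @ Xc
    total_var = np.trace(cov)
    if total_var <= 1e-14:
        raise ValueError("degenerate PCA model: features have zero variance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    comps = _fix_signs(evecs[:, order].T)
    return PCAModel(mean=mean, components=comps, eigenvalues=evals)


def project(features: np.ndarray, model: PCAModel, n: int = 2) -> np.ndarray:
    """Project features onto the first ``n`` principal components."""
    if n < 1 or n > model.n_components:
        raise ValueError(f"n must be in 1..{model.n_components}")
    X = np.asarray(features, dtype=float)
    return (X - model.mean) @ model.components[:n].T


def kmeans_cluster(coords: np.ndarray, k: int, seed: int = 0) -> ClusterResult:
    """K-means (k-means++ init, Lloyd iterations) on PC coordinates.

    Deterministic for a given seed; clusters are relabeled by descending
    population so "cluster 0" is always the most populated state.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = coords.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in 1..{n}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=10,
        max_iter=500,
        tol=1e-6,
        random_state=seed,
        algorithm="lloyd",
    ).fit(coords)
    labels = km.labels_
    centroids = km.cluster_centers_
    # stable reorder by descending population, centroid-norm tiebreak
    counts = np.bincount(labels, minlength=k)
    order = np.lexsort((np.arange(k), -counts))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    result = ClusterResult(
        labels=relabel[labels],
        centroids=centroids[order],
        representative_frames=np.full(k, -1, dtype=int),
    )
    result.representative_frames = representative_frames(coords, result)
    return result


def representative_frames(coords: np.ndarray, result: ClusterResult) -> np.ndarray:
    """Per cluster, the member frame nearest (Euclidean) its centroid.

    Ties break to the lowest frame index; empty clusters get −1.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    reps = np.full(result.k, -1, dtype=int)
    for c in range(result.k):
        members = np.flatnonzero(result.labels == c)
        if members.size == 0:
            continue
        d = np.linalg.norm(coords[members] - result.centroids[c], axis=1)
        reps[c] = members[np.argmin(d)]  # argmin returns the first (lowest) index
    return reps


def match_external_representative(
    coords: np.ndarray,
    result: ClusterResult,
    reference_point: np.ndarray,
    radius: float = 1.0,
) -> tuple[int, int, bool]:
    """Match a reference PC point to this ensemble's nearest cluster.

    Returns ``(cluster_index, frame_index, frame_fallback)``. The cluster
    whose representative frame lies nearest the reference wins; if no
    centroid lies within ``radius`` of the reference there is no adequate
    cluster, and the single nearest frame is returned instead with the
    fallback flag set.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    ref = np.asarray(reference_point, dtype=float)
    cent_d = np.linalg.norm(result.centroids - ref, axis=1)
    if cent_d.min() <= radius:
        valid = np.flatnonzero(result.representative_frames >= 0)
        rep_pts = coords[result.representative_frames[valid]]
        rep_d = np.linalg.norm(rep_pts - ref, axis=1)
        c = int(valid[np.argmin(rep_d)])
        return c, int(result.representative_frames[c]), False
    frame = int(np.argmin(np.linalg.norm(coords - ref, axis=1)))
    return int(result.labels[frame]), frame, True
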