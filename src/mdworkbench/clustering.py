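"""Conformational clustering by intelligent Minkowski-weighted K-means.

The Amorim–Hennig procedure used here runs in two stages:

1. **iMWK-means** — anomalous-pattern initialisation repeatedly extracts the
   point farthest from the grand centre, grows a tentative cluster around it
   until stable, and removes it; surviving clusters (size > ``theta``) fix
   both the number of clusters K and the seed centroids.  Minkowski-weighted
   K-means then iterates assignment, centroid and weight updates with
   per-cluster per-feature weights
   ``w_kv = 1 / Σ_u (D_kv / D_ku)^(1/(p−1))``
   where ``D_kv`` is the within-cluster dispersion of feature v.  The
   objective ``Σ_k Σ_{i∈k} Σ_v w_kv^p |x_iv − c_kv|^p`` never increases.
2. **Explicit rescaling + K-means** — features are multiplied by the learned
   weights (averaged over clusters to one per-feature rescaling vector),
   shrinking the axes the first stage found uninformative; the
   anomalous-pattern initialisation is re-run in the rescaled space to fix
   the final K, and a standard K-means from those seeds gives the final
   labels.

With the default Minkowski exponent p = 2 distances are Euclidean and
centroids are means.  Frame feature vectors are flattened heavy-atom
coordinates of a selection (e.g. residues within 10 Å of the DNA), so the
learned weights double as a per-coordinate relevance measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import cdist

from .trajectory import EmptySelectionError, Trajectory

__all__ = [
    "FrameFeatures",
    "ClusterModel",
    "extract_features",
    "select_within",
    "imwk_fit",
    "rescale_and_kmeans",
    "amorim_hennig",
    "occupancy_table",
    "representative_frame",
]


@dataclass
class FrameFeatures:
    """frames × features matrix of flattened selected-atom coordinates (Å)."""

    X: np.ndarray                      # (n_frames, 3 * n_atoms)
    descriptors: list[tuple]           # (atom index, axis) per feature
    labels: np.ndarray | None = None   # source system per frame

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values")
        if len(self.descriptors) != self.X.shape[1]:
            raise ValueError("descriptor count != feature count")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]


@dataclass
class ClusterModel:
    """Result of (i)MWK-means: cluster count, per-cluster feature weights,
    centroids, per-frame labels and the final objective value."""

    K: int
    p: float
    weights: np.ndarray            # (K, V), rows sum to 1
    centroids: np.ndarray          # (K, V) — in rescaled space after the final K-means
    labels: np.ndarray             # (n_frames,) ints in [0, K)
    objective: float
    theta: int = 1                 # anomalous-cluster discard threshold used
    objective_history: list[float] = field(default_factory=list)
    rescale: np.ndarray | None = None  # per-feature multiplier used for the final pass

    def __post_init__(self) -> None:
        if self.objective < -1e-9:
            raise ValueError("objective must be non-negative")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("per-cluster weights must sum to 1")
        if self.labels.min() < 0 or self.labels.max() >= self.K:
            raise ValueError("labels out of range")


def select_within(traj: Trajectory, target_mask: np.ndarray, cutoff: float,
                  reference_frame: int = 0, heavy_only: bool = True) -> np.ndarray:
    """Atom indices of residues with any atom within ``cutoff`` Å of the
    target atoms, evaluated on one reference frame (fixed feature schema).

    Returns all (heavy) atoms of qualifying residues, excluding the target
    residues themselves.
    """
    top = traj.topology
    target_idx = np.flatnonzero(target_mask)
    if target_idx.size == 0:
        raise EmptySelectionError("empty target selection")
    X = traj.coords[reference_frame]
    d = cdist(X, X[target_idx]).min(axis=1)
    res_keys = np.asarray(
        [f"{s}|{r}" for s, r in zip(top.segids, top.resids)], dtype=object
    )
    near_res = set(res_keys[(d <= cutoff) & ~np.isin(np.arange(top.n_atoms), target_idx)])
    target_res = set(res_keys[target_idx])
    keep_res = near_res - target_res
    mask = np.isin(res_keys, sorted(keep_res))
    if heavy_only:
        mask &= top.heavy
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise EmptySelectionError(f"no residues within {cutoff} Å of the target")
    return idx


def extract_features(traj: Trajectory, selection: np.ndarray) -> FrameFeatures:
    """Row f = concatenated (x, y, z) of the selected atoms in frame f."""
    selection = np.asarray(selection, dtype=np.intp)
    if selection.size == 0:
        raise EmptySelectionError("empty atom selection")
    X = traj.coords[:, selection, :].reshape(traj.n_frames, -1)
    descriptors = [(int(a), ax) for a in selection for ax in ("x", "y", "z")]
    return FrameFeatures(X=X, descriptors=descriptors, labels=traj.labels.copy())


def _minkowski_center(col: np.ndarray, p: float) -> float:
    """argmin_c Σ |x − c|^p for one feature (mean when p = 2, median when p = 1)."""
    if p == 2.0:
        return float(col.mean())
    if p == 1.0:
        return float(np.median(col))
    res = minimize_scalar(
        lambda c: float(np.sum(np.abs(col - c) ** p)),
        bounds=(float(col.min()), float(col.max())),
        method="bounded",
    )
    return float(res.x)


def _centers(X: np.ndarray, p: float) -> np.ndarray:
    if p == 2.0:
        return X.mean(axis=0)
    return np.asarray([_minkowski_center(X[:, v], p) for v in range(X.shape[1])])


def _weighted_pdist(X: np.ndarray, centroids: np.ndarray, weights: np.ndarray,
                    p: float) -> np.ndarray:
    """(n, K) matrix of Σ_v w_kv^p |x_v − c_kv|^p."""
    n, K = X.shape[0], centroids.shape[0]
    out = np.empty((n, K))
    wp = weights ** p
    for k in range(K):
        out[:, k] = np.abs(X - centroids[k]) ** p @ wp[k]
    return out


def _update_weights(X: np.ndarray, centroids: np.ndarray, labels: np.ndarray,
                    p: float, K: int) -> np.ndarray:
    """w_kv = 1 / Σ_u (D_kv / D_ku)^(1/(p−1)), D the within-cluster dispersion.

    Zero dispersions are floored at 1e−12 × the mean dispersion of the
    cluster (or an absolute floor when the whole cluster is degenerate).
    """
    V = X.shape[1]
    W = np.empty((K, V))
    for k in range(K):
        members = X[labels == k]
        D = np.sum(np.abs(members - centroids[k]) ** p, axis=0)
        mean_D = D.mean()
        eps = 1e-12 * mean_D if mean_D > 0 else 1e-12
        D = np.maximum(D, eps)
        if p == 1.0:
            w = np.zeros(V)
            w[np.argmin(D)] = 1.0  # limit of the exponent 1/(p−1) -> inf
        else:
            expo = 1.0 / (p - 1.0)
            w = 1.0 / np.sum((D[:, None] / D[None, :]) ** expo, axis=1)
        W[k] = w / w.sum()
    return W


def _objective(X, centroids, weights, labels, p) -> float:
    d = _weighted_pdist(X, centroids, weights, p)
    return float(d[np.arange(X.shape[0]), labels].sum())


def _tentative_weights(members: np.ndarray, ct: np.ndarray, p: float) -> np.ndarray:
    """Minkowski weights from the tentative cluster's own dispersions."""
    V = ct.shape[0]
    D = np.sum(np.abs(members - ct) ** p, axis=0)
    mean_D = D.mean()
    eps = 1e-12 * mean_D if mean_D > 0 else 1e-12
    D = np.maximum(D, eps)
    if p == 1.0:
        w = np.zeros(V)
        w[np.argmin(D)] = 1.0
    else:
        w = 1.0 / np.sum((D[:, None] / D[None, :]) ** (1.0 / (p - 1.0)), axis=1)
    return w / w.sum()


def _anomalous_pattern_init(X: np.ndarray, p: float, theta: int,
                            max_iter: int = 100,
                            adaptive_weights: bool = True) -> np.ndarray:
    """Seed centroids by repeated farthest-point cluster extraction.

    Each extraction starts from the point farthest from the grand centre and
    iterates a two-centre weighted assignment (tentative centroid vs grand
    centre), a Minkowski-centre update and — when ``adaptive_weights`` is on
    — a weight update driven by the tentative cluster's feature dispersions,
    so the growing cluster learns which features define it.  In an already
    rescaled space the weights stay uniform (``adaptive_weights=False``).
    Extracted clusters of size <= ``theta`` are discarded; the survivors fix
    K and the seed centroids.
    """
    V = X.shape[1]
    grand = _centers(X, p)
    remaining = np.arange(X.shape[0])
    centroids, sizes = [], []
    while remaining.size:
        R = X[remaining]
        w = np.full(V, 1.0 / V)
        far = int(np.argmax(np.abs(R - grand) ** p @ (w ** p)))
        ct = R[far].copy()
        members = np.asarray([far])
        for _ in range(max_iter):
            wp = w ** p
            d_c = np.abs(R - ct) ** p @ wp
            d_grand = np.abs(R - grand) ** p @ wp
            new_members = np.flatnonzero(d_c < d_grand)
            if new_members.size == 0:
                new_members = np.asarray([far])
            stable = np.array_equal(new_members, members)
            members = new_members
            ct = _centers(R[members], p)
            if adaptive_weights:
                w = _tentative_weights(R[members], ct, p)
            if stable:
                break
        if members.size > theta:
            centroids.append(ct)
            sizes.append(members.size)
        remaining = np.delete(remaining, members)
    if not centroids:
        raise ValueError(f"anomalous-pattern init found no cluster larger than theta={theta}")
    order = np.argsort(sizes)[::-1]  # largest first: stable cluster numbering
    return np.stack([centroids[i] for i in order])


def imwk_fit(
    features: FrameFeatures | np.ndarray,
    p: float = 2.0,
    theta: int = 1,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> ClusterModel:
    """Intelligent Minkowski-weighted K-means.

    K is selected by the anomalous-pattern initialisation; the main loop
    then iterates assignment / Minkowski-centre / weight updates to a fixed
    point.  Raises if all rows are identical (no cluster structure) and
    asserts the objective never increases.
    """
    X = features.X if isinstance(features, FrameFeatures) else np.asarray(features, float)
    if p <= 1.0:
        raise ValueError("Minkowski exponent p must be > 1 (weights need 1/(p−1))")
    if np.all(X == X[0]):
        raise ValueError("all feature rows identical: clustering is degenerate")
    centroids = _anomalous_pattern_init(X, p, theta)
    K, V = centroids.shape[0], X.shape[1]
    weights = np.full((K, V), 1.0 / V)
    labels = np.argmin(_weighted_pdist(X, centroids, weights, p), axis=1)
    history = [_objective(X, centroids, weights, labels, p)]
    for _ in range(max_iter):
        # centroid update
        for k in range(K):
            members = X[labels == k]
            if members.size:
                centroids[k] = _centers(members, p)
        # weight update
        weights = _update_weights(X, centroids, labels, p, K)
        # assignment update
        new_labels = np.argmin(_weighted_pdist(X, centroids, weights, p), axis=1)
        # keep emptied clusters' centroids in place; they may recapture points
        obj = _objective(X, centroids, weights, new_labels, p)
        if obj > history[-1] + 1e-6 * max(1.0, abs(history[-1])):
            raise AssertionError("iMWK objective increased — update order broken")
        converged = np.array_equal(new_labels, labels) and history[-1] - obj <= tol
        labels = new_labels
        history.append(obj)
        if converged:
            break
    # drop clusters that ended empty and renumber
    occupied = np.unique(labels)
    remap = {int(k): i for i, k in enumerate(occupied)}
    labels = np.asarray([remap[int(l)] for l in labels], dtype=np.intp)
    centroids = centroids[occupied]
    weights = weights[occupied]
    weights = weights / weights.sum(axis=1, keepdims=True)
    return ClusterModel(
        K=len(occupied),
        p=p,
        weights=weights,
        centroids=centroids,
        labels=labels,
        objective=history[-1],
        theta=theta,
        objective_history=history,
    )


def rescale_and_kmeans(
    features: FrameFeatures | np.ndarray,
    model: ClusterModel,
    max_iter: int = 300,
    reselect_k: bool = True,
) -> ClusterModel:
    """Explicit rescaling followed by standard K-means.

    The per-cluster weights are averaged to one per-feature rescaling
    vector and the features are multiplied by it, shrinking the axes the
    first stage found uninformative.  By default the anomalous-pattern
    initialisation is then re-run *in the rescaled space* — where noise
    features no longer distort the cluster count — to fix K and seed a
    standard K-means; ``reselect_k=False`` instead keeps the first stage's
    K and centroids (useful when K is externally known).
    """
    from sklearn.cluster import KMeans

    X = features.X if isinstance(features, FrameFeatures) else np.asarray(features, float)
    w = model.weights.mean(axis=0)
    Xs = X * w
    if reselect_k:
        init = _anomalous_pattern_init(Xs, model.p, theta=model.theta, adaptive_weights=False)
    else:
        init = model.centroids * w
    km = KMeans(
        n_clusters=init.shape[0], init=init, n_init=1, max_iter=max_iter,
        tol=1e-12, algorithm="lloyd", random_state=0,
    ).fit(Xs)
    labels = km.labels_.astype(np.intp)
    K = init.shape[0]
    return ClusterModel(
        K=K,
        p=model.p,
        theta=model.theta,
        weights=np.tile(w / w.sum(), (K, 1)),
        centroids=km.cluster_centers_,
        labels=labels,
        objective=float(km.inertia_),
        objective_history=model.objective_history + [float(km.inertia_)],
        rescale=w,
    )


def amorim_hennig(
    features: FrameFeatures | np.ndarray,
    p: float = 2.0,
    theta: int = 1,
) -> ClusterModel:
    """The full two-stage procedure: iMWK-means, then rescaling + K-means."""
    return rescale_and_kmeans(features, imwk_fit(features, p=p, theta=theta))


def occupancy_table(labels: np.ndarray, systems: np.ndarray) -> pd.DataFrame:
    """Per-system percentage of frames in each cluster (rows sum to 100)."""
    labels = np.asarray(labels)
    systems = np.asarray(systems)
    if len(labels) != len(systems):
        raise ValueError("labels and system labels differ in length")
    if len(labels) == 0:
        raise ValueError("empty label sequence")
    clusters = np.unique(labels)
    rows = {}
    for sys_name in dict.fromkeys(systems.tolist()):
        mask = systems == sys_name
        if not mask.any():
            raise ValueError(f"system {sys_name!r} has no frames")
        counts = np.asarray([(labels[mask] == k).sum() for k in clusters], dtype=float)
        rows[sys_name] = 100.0 * counts / counts.sum()
    return pd.DataFrame(rows, index=[f"cluster_{k}" for k in clusters]).T


def representative_frame(
    features: FrameFeatures | np.ndarray, labels: np.ndarray, cluster: int
) -> int:
    """Member frame with the smallest RMSD from the cluster's mean structure
    (coordinate-wise mean); ties break to the lowest frame index."""
    X = features.X if isinstance(features, FrameFeatures) else np.asarray(features, float)
    members = np.flatnonzero(np.asarray(labels) == cluster)
    if members.size == 0:
        raise ValueError(f"cluster {cluster} is empty")
    mean = X[members].mean(axis=0)
    rmsd = np.sqrt(np.mean((X[members] - mean) ** 2, axis=1))
    return int(members[np.argmin(rmsd)])
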