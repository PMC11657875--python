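"""Profile feature vectors, Ward clustering and Davies-Bouldin selection.

A spine enters the clustering as a 175-dimensional vector: dimensions
1-100 are its diameter profile resampled to 100 points (attachment to
tip, nm), dimensions 101-175 its 3D length repeated 75 times.  Before
clustering, lengths are rescaled by a single dataset-wide factor so that
the grand mean of the length dimensions equals the grand mean of the
diameter dimensions, balancing the two blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from spinemorph.morphometry import WidthProfile

__all__ = [
    "N_PROFILE_DIMS",
    "N_LENGTH_DIMS",
    "FeatureMatrix",
    "ClusterModel",
    "resample_profile",
    "build_feature_matrix",
    "ward_linkage",
    "ward_cluster",
    "davies_bouldin",
    "select_k",
    "class_mean_profiles",
    "fit_classes",
]

N_PROFILE_DIMS = 100
N_LENGTH_DIMS = 75


def resample_profile(profile: WidthProfile, n: int = N_PROFILE_DIMS) -> np.ndarray:
    """Linearly interpolate the diameters at ``n`` equally spaced arc
    positions spanning [0, spine_length]."""
    if len(profile.s) < 2:
        raise ValueError(f"spine {profile.spine_id}: need >= 2 profile samples")
    positions = np.linspace(0.0, profile.s[-1], n)
    return np.interp(positions, profile.s, profile.d)


@dataclass
class FeatureMatrix:
    """Stacked 175-dim feature vectors plus the length rescale factor."""

    X: np.ndarray
    spine_ids: list[str]
    length_scale_factor: float

    @property
    def n_spines(self) -> int:
        return self.X.shape[0]


def build_feature_matrix(
    profiles: np.ndarray | list[WidthProfile],
    lengths: np.ndarray | None = None,
    spine_ids: list[str] | None = None,
) -> FeatureMatrix:
    """Assemble the (n, 175) clustering input.

    ``profiles`` is either an (n, 100) array of resampled diameters or a
    list of :class:`WidthProfile` (resampled here, with lengths taken from
    the profiles).  The scale factor is
    grand-mean(diameters) / mean(lengths).
    """
    if isinstance(profiles, np.ndarray):
        P = np.asarray(profiles, dtype=float)
        if lengths is None:
            raise ValueError("lengths required when passing a raw profile array")
        L = np.asarray(lengths, dtype=float)
        ids = spine_ids or [f"spine{i}" for i in range(len(P))]
    else:
        P = np.vstack([resample_profile(p) for p in profiles])
        L = np.array([p.length for p in profiles])
        ids = [p.spine_id for p in profiles]
    if P.ndim != 2 or P.shape[1] != N_PROFILE_DIMS:
        raise ValueError(f"profiles must be (n, {N_PROFILE_DIMS})")
    if len(P) < 2:
        raise ValueError("need >= 2 spines to build features")
    mean_length = L.mean()
    if mean_length == 0:
        raise ValueError("zero mean spine length")
    factor = P.mean() / mean_length
    X = np.hstack([P, np.tile((L * factor)[:, None], (1, N_LENGTH_DIMS))])
    return FeatureMatrix(X=X, spine_ids=list(ids), length_scale_factor=float(factor))


def ward_linkage(X: np.ndarray) -> np.ndarray:
    """Ward/Euclidean agglomeration; deterministic for a given input order
    (ties broken by merge height sorting, then lowest cluster indices)."""
    return linkage(np.asarray(X, dtype=float), method="ward")


def ward_cluster(X: np.ndarray, k: int, Z: np.ndarray | None = None) -> np.ndarray:
    """Cut the Ward tree at ``k`` clusters; labels in 1..k."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range 1..{n}")
    if Z is None:
        Z = ward_linkage(X)
    return fcluster(Z, t=k, criterion="maxclust")


def davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst
    (S_i + S_j) / M_ij, with S the mean member-to-centroid distance and M
    the centroid separation.  Lower is better."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("Davies-Bouldin needs >= 2 clusters")
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in uniq])
    scatter = np.array(
        [
            np.linalg.norm(X[labels == c] - centroids[i], axis=1).mean()
            for i, c in enumerate(uniq)
        ]
    )
    M = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    off = ~np.eye(k, dtype=bool)
    if np.any(M[off] == 0):
        raise ValueError("coincident centroids: Davies-Bouldin undefined")
    ratios = (scatter[:, None] + scatter[None, :]) / np.where(off, M, np.inf)
    return float(np.max(np.where(off, ratios, -np.inf), axis=1).mean())


def select_k(
    X: np.ndarray,
    k_range: range | tuple[int, int] = (2, 8),
    Z: np.ndarray | None = None,
) -> tuple[int, dict[int, float]]:
    """Pick the cluster count minimizing Davies-Bouldin over candidates.

    Returns ``(best_k, {k: db_index})``; ties go to the smaller k.
    """
    X = np.asarray(X, dtype=float)
    if isinstance(k_range, tuple):
        candidates = range(k_range[0], k_range[1] + 1)
    else:
        candidates = k_range
    candidates = [k for k in candidates if 2 <= k <= X.shape[0] - 1]
    if not candidates:
        raise ValueError("no valid candidate k in range")
    if Z is None:
        Z = ward_linkage(X)
    curve: dict[int, float] = {}
    for k in candidates:
        labels = fcluster(Z, t=k, criterion="maxclust")
        curve[k] = davies_bouldin(X, labels)
    best = min(curve, key=lambda k: (curve[k], k))
    return best, curve


@dataclass
class ClusterModel:
    """Fitted clustering: linkage tree, selected k, labels and DB curve."""

    linkage: np.ndarray
    k: int
    labels: np.ndarray
    db_curve: dict[int, float]
    length_scale_factor: float
    spine_ids: list[str] = field(default_factory=list)

    def labels_by_spine(self) -> dict[str, int]:
        return {sid: int(lab) for sid, lab in zip(self.spine_ids, self.labels)}


def fit_classes(
    features: FeatureMatrix, k: int | None = None, k_range: tuple[int, int] = (2, 8)
) -> ClusterModel:
    """Cluster a feature matrix; select k by Davies-Bouldin unless given."""
    Z = ward_linkage(features.X)
    if k is None:
        k, curve = select_k(features.X, k_range, Z=Z)
    else:
        _, curve = select_k(features.X, k_range, Z=Z)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterModel(
        linkage=Z,
        k=int(k),
        labels=labels,
        db_curve=curve,
        length_scale_factor=features.length_scale_factor,
        spine_ids=features.spine_ids,
    )


def class_mean_profiles(
    profiles: np.ndarray,
    lengths: np.ndarray,
    labels: np.ndarray,
) -> dict[int, tuple[np.ndarray, float]]:
    """Per-class mean resampled profile and mean spine length.

    The mean profile lives on a normalized arc axis; its physical axis is
    obtained by scaling to the class's mean length (as in class-average
    profile displays).
    """
    profiles = np.asarray(profiles, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    labels = np.asarray(labels)
    out: dict[int, tuple[np.ndarray, float]] = {}
    for c in np.unique(labels):
        mask = labels == c
        if not mask.any():
            raise ValueError(f"class {c} is empty")
        out[int(c)] = (profiles[mask].mean(axis=0), float(lengths[mask].mean()))
    return out
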