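"""Spatial k-means clustering of pooled foci and elbow-based model selection.

Foci are clustered in raw millimetre coordinates (the three axes share units,
so no standardisation).  K is chosen by an elbow rule formalised as: the
smallest K whose within-cluster sum of squares drops to ``ratio`` (default
1/10) of the single-cluster SSE, plus a fixed ``offset`` (default 2) that
takes the upper end of the plausible elbow range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConfigError, EmptyInputError, ValidationError


@dataclass
class ClusterModel:
    """A fitted spatial partition of the foci."""

    k: int
    centroids: np.ndarray          # (k, 3) mm, full precision
    assignments: np.ndarray        # (n,) ints in [0, k)
    sse: float                     # total within-cluster sum of squares, mm^2
    seed: int | None
    n_restarts: int


def _total_ss(coords: np.ndarray) -> float:
    return float(((coords - coords.mean(axis=0)) ** 2).sum())


def fit_kmeans(coords, k: int, seed: int | None = 0,
               n_restarts: int = 10) -> ClusterModel:
    """Best-of-restarts Lloyd k-means from k-means++ initialisation.

    Deterministic given ``seed``; empty clusters are repaired internally by
    reseeding with the farthest points (scikit-learn's relocation).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError("coords must be an (n, 3) array of mm positions")
    if len(coords) == 0:
        raise EmptyInputError("no foci to cluster")
    n_distinct = len(np.unique(coords, axis=0))
    if not 1 <= k <= n_distinct:
        raise ValidationError(
            f"k={k} must be in [1, number of distinct points={n_distinct}]"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    km.fit(coords)
    return ClusterModel(k=k, centroids=km.cluster_centers_.copy(),
                        assignments=km.labels_.astype(int),
                        sse=float(km.inertia_), seed=seed, n_restarts=n_restarts)


def elbow_scan(coords, k_min: int = 1, k_max: int = 40, seed: int | None = 0,
               n_restarts: int = 10) -> pd.DataFrame:
    """SSE per K over a scan range (shared seed policy across K).

    Returns a frame with columns ``k``, ``sse`` and ``blip`` - the latter
    flags the occasional restart-noise K where SSE rose relative to K-1.
    """
    coords = np.asarray(coords, dtype=float)
    if not 1 <= k_min <= k_max:
        raise ConfigError("need 1 <= k_min <= k_max")
    k_max = min(k_max, len(np.unique(coords, axis=0)))
    ks = list(range(k_min, k_max + 1))
    sses = [fit_kmeans(coords, k, seed=seed, n_restarts=n_restarts).sse for k in ks]
    blip = [False] + [sses[i] > sses[i - 1] + 1e-9 for i in range(1, len(sses))]
    return pd.DataFrame({"k": ks, "sse": sses, "blip": blip})


def select_k(report: pd.DataFrame, ratio: float = 0.1, offset: int = 2,
             sse_1: float | None = None) -> int:
    """Elbow rule: (smallest K with SSE(K) <= ratio * SSE(1)) + offset.

    SSE(1) is taken from the scan if K=1 was scanned, else from ``sse_1``
    (the total sum of squares, computable in closed form).  The result is
    clamped to the scanned range; clamping is logged.
    """
    if not 0 < ratio <= 1:
        raise ConfigError("ratio must be in (0, 1]")
    if offset < 0:
        raise ConfigError("offset must be >= 0")
    ks = report["k"].to_numpy()
    sses = report["sse"].to_numpy()
    if 1 in ks:
        base = float(sses[ks == 1][0])
    elif sse_1 is not None:
        base = float(sse_1)
    else:
        raise ConfigError("scan does not include K=1; pass sse_1 explicitly")
    hit = np.flatnonzero(sses <= ratio * base)
    if len(hit) == 0:
        raise ConfigError(
            f"no scanned K reaches SSE <= {ratio} * SSE(1); widen the scan"
        )
    k_star = int(ks[hit[0]]) + offset
    lo, hi = int(ks.min()), int(ks.max())
    clamped = min(max(k_star, lo), hi)
    if clamped != k_star:
        import logging
        logging.getLogger(__name__).info(
            "selected K %d clamped to scanned range [%d, %d]", k_star, lo, hi)
    return clamped


def centroid_table(model: ClusterModel) -> pd.DataFrame:
    """Display table of centroids: ids ``cl_0..cl_{K-1}`` in fit order, mm
    coordinates rounded to integers (full precision stays on the model)."""
    ints = np.rint(model.centroids).astype(int)
    return pd.DataFrame(
        {"x": ints[:, 0], "y": ints[:, 1], "z": ints[:, 2]},
        index=pd.Index([f"cl_{i}" for i in range(model.k)], name="cluster_id"),
    )


class ElbowKMeans(BaseEstimator, ClusterMixin):
    """k-means over foci coordinates with elbow-based selection of K.

    Parameters
    ----------
    n_clusters : int or 'auto', default 'auto'
        Fixed K, or elbow selection over ``[k_min, k_max]``.
    k_min, k_max : int
        Scan range for the elbow rule.
    ratio : float, default 0.1
        SSE(K)/SSE(1) level defining the elbow crossing.
    offset : int, default 2
        Added to the crossing K (upper end of the plausible range).
    n_restarts : int, default 10
        k-means++ restarts per K; best SSE kept.
    random_state : int, optional

    Attributes
    ----------
    n_clusters_ : int
    cluster_centers_ : ndarray of shape (K, 3)
    labels_ : ndarray of shape (n,)
    inertia_ : float
    elbow_report_ : pandas.DataFrame or None
        K/SSE scan (only when ``n_clusters='auto'``).
    """

    def __init__(self, n_clusters="auto", k_min: int = 1, k_max: int = 40,
                 ratio: float = 0.1, offset: int = 2, n_restarts: int = 10,
                 random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.k_min = k_min
        self.k_max = k_max
        self.ratio = ratio
        self.offset = offset
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.n_clusters == "auto":
            report = elbow_scan(X, self.k_min, self.k_max,
                                seed=self.random_state, n_restarts=self.n_restarts)
            k = select_k(report, self.ratio, self.offset, sse_1=_total_ss(X))
            self.elbow_report_ = report
        else:
            k = int(self.n_clusters)
            self.elbow_report_ = None
        model = fit_kmeans(X, k, seed=self.random_state, n_restarts=self.n_restarts)
        self.n_clusters_ = model.k
        self.cluster_centers_ = model.centroids
        self.labels_ = model.assignments
        self.inertia_ = model.sse
        self.model_ = model
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        d = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)

    def cluster_ids(self) -> list[str]:
        check_is_fitted(self, "n_clusters_")
        return [f"cl_{i}" for i in range(self.n_clusters_)]
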