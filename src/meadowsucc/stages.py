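"""Succession-stage assignment by Ward agglomerative clustering.

Quadrats are clustered on their functional-group biomass shares plus
species richness and aboveground biomass (all columns standardised to unit
variance), with Euclidean geometry
and the Ward minimum-variance criterion; the tree is cut at ``n_clusters``
(default 4, the stage count of the design).  Clusters are then ordered into
the succession sequence: descending mean sedge share (Stage 1 is the
sedge-dominated community), ties broken by ascending mean toxic-forb share,
then by cluster label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .community import community_summary
from .io import FUNCTIONAL_GROUPS, FunctionalGroupMap, SurveyTable

__all__ = [
    "StageAssignment",
    "feature_matrix",
    "ward_cluster",
    "order_stages",
    "WardStageClusterer",
    "assign_stages",
]

logger = logging.getLogger(__name__)

_SHARE_COLUMNS = [f"share_{g}" for g in FUNCTIONAL_GROUPS]


@dataclass
class StageAssignment:
    """Clustered stage labels plus the merge tree that produced them."""

    quadrat_ids: list[str]
    cluster_labels: np.ndarray            # per quadrat, 0-based
    stage_of_cluster: dict[int, int]      # cluster label -> stage 1..k
    linkage: np.ndarray                   # scipy linkage matrix

    @property
    def stages(self) -> np.ndarray:
        return np.array([self.stage_of_cluster[c] for c in self.cluster_labels])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"quadrat_id": self.quadrat_ids,
             "cluster": self.cluster_labels,
             "stage": self.stages}
        ).set_index("quadrat_id")


def feature_matrix(
    table: SurveyTable, fgmap: FunctionalGroupMap
) -> pd.DataFrame:
    """Default clustering features: group shares plus SR and AGB, all z-scored.

    Every column is standardised to mean 0 / sd 1 before clustering: Ward on
    Euclidean distances is scale-sensitive, and mixing raw compositional
    shares (sd ~ 0.05) with unit-variance columns would let the latter
    dominate the geometry.  Constant columns are dropped with a logged
    warning (they carry no clustering information).
    """
    summ = community_summary(table, fgmap)
    feats = summ[_SHARE_COLUMNS].copy()
    cov = table.covariate_frame()
    feats["sr"] = cov["sr"].astype(float)
    feats["agb"] = cov["agb"].astype(float)
    constant = [c for c in feats.columns if feats[c].std(ddof=0) == 0]
    if constant:
        logger.warning("dropping constant feature column(s) %r", constant)
        feats = feats.drop(columns=constant)
    return (feats - feats.mean()) / feats.std(ddof=0)


class WardStageClusterer(ClusterMixin, BaseEstimator):
    """Ward agglomerative clustering with a fixed-k tree cut.

    Parameters
    ----------
    n_clusters : int, default 4
        Number of clusters to cut the merge tree at.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        0-based cluster labels.
    linkage_ : ndarray
        scipy linkage matrix (merge pairs and heights).
    """

    def __init__(self, n_clusters: int = 4):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        n = X.shape[0]
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > n:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds n_samples={n}")
        if n == 1:
            self.linkage_ = np.empty((0, 4))
            self.labels_ = np.zeros(1, dtype=int)
            return self
        self.linkage_ = hierarchy.linkage(X, method="ward")
        flat = hierarchy.fcluster(self.linkage_, t=self.n_clusters,
                                  criterion="maxclust")
        self.labels_ = np.asarray(flat) - 1
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def ward_cluster(features, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Cluster a feature matrix; returns (labels, linkage matrix)."""
    model = WardStageClusterer(n_clusters=k).fit(np.asarray(features, dtype=float))
    return model.labels_, model.linkage_


def order_stages(
    cluster_labels: np.ndarray,
    sedge_share: np.ndarray,
    toxic_share: np.ndarray,
) -> dict[int, int]:
    """Rank clusters into stages: descending sedge, then ascending toxic.

    An exact tie on both keys falls back to cluster label order (logged).
    """
    labels = np.asarray(cluster_labels)
    keys = []
    for c in np.unique(labels):
        mask = labels == c
        keys.append((-float(np.mean(sedge_share[mask])),
                     float(np.mean(toxic_share[mask])), int(c)))
    order = sorted(keys)
    for a, b in zip(order, order[1:]):
        if a[:2] == b[:2]:
            logger.warning(
                "clusters %d and %d tie on sedge and toxic shares; "
                "breaking by label order", a[2], b[2])
    return {c: rank + 1 for rank, (_, _, c) in enumerate(order)}


def assign_stages(
    table: SurveyTable,
    fgmap: FunctionalGroupMap,
    n_clusters: int = 4,
) -> StageAssignment:
    """Cluster a survey and order the clusters into the succession sequence."""
    feats = feature_matrix(table, fgmap)
    labels, linkage = ward_cluster(feats.to_numpy(), n_clusters)
    summ = community_summary(table, fgmap)
    stage_of = order_stages(
        labels,
        summ["share_sedge"].to_numpy(),
        summ["share_toxic_forb"].to_numpy(),
    )
    return StageAssignment(
        quadrat_ids=list(feats.index),
        cluster_labels=labels,
        stage_of_cluster=stage_of,
        linkage=linkage,
    )
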