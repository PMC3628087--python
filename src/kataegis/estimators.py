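"""Scikit-learn-style estimators for the detection core.

`IMDPartitioner` is a two-group 1-D clusterer over intermutational
distances; `KataegisDetector` wraps the whole detection pipeline (IMDs ->
partition -> threshold -> cluster calls) behind a fit interface with
per-mutation labels, so it composes with sklearn tooling
(get_params/set_params, clone).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .catalog import MutationCatalog


class IMDPartitioner(ClusterMixin, BaseEstimator):
    """Two-group k-means over intermutational distances.

    Clusters 1-D IMD values (bp) into a proximal and a distal group by
    Lloyd k-means on log10(IMD), initialized deterministically at the
    ``init_quantiles`` of the log-distances, and derives the
    cluster-calling threshold as the (1 - exclusion) quantile of the
    distal group.

    Parameters
    ----------
    exclusion : float, default 0.99
        Fraction of the distal group the threshold must exclude.
    log_scale : bool, default True
        Cluster log10(IMD) rather than raw distances; IMDs are bimodal on
        the log scale (hundreds of bp within kataegic stretches vs tens to
        hundreds of kb between scattered singlets).
    init_quantiles : pair of float, default (0.10, 0.90)
        Deterministic centroid initialization quantiles.
    max_iter : int, default 300

    Attributes
    ----------
    labels_ : ndarray
        0 for the proximal group (smaller median), 1 for distal.
    median_proximal_, median_distal_ : float
        Group medians in bp.
    threshold_ : float
        Calling threshold in bp.
    cluster_centers_ : ndarray of shape (2, 1)
        Centroids on the clustering scale (log10 bp by default).
    """

    def __init__(
        self,
        exclusion: float = 0.99,
        log_scale: bool = True,
        init_quantiles: tuple[float, float] = (0.10, 0.90),
        max_iter: int = 300,
    ):
        self.exclusion = exclusion
        self.log_scale = log_scale
        self.init_quantiles = init_quantiles
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("IMDPartitioner expects a single column of distances")
        values = X[:, 0]
        if len(values) < 4:
            raise ValueError("need at least 4 IMD entries to partition")
        if (values < 1).any():
            raise ValueError("IMDs must be >= 1 bp")
        scale = np.log10(values) if self.log_scale else values
        if np.unique(scale).size < 2:
            raise ValueError("degenerate partition: all IMDs identical")
        init = np.quantile(scale, self.init_quantiles).reshape(2, 1)
        if init[0, 0] == init[1, 0]:
            # heavily tied data: fall back to the extreme values
            init = np.array([[scale.min()], [scale.max()]])
        km = KMeans(
            n_clusters=2, init=init, n_init=1, max_iter=self.max_iter,
            algorithm="lloyd",
        ).fit(scale.reshape(-1, 1))
        raw_labels = km.labels_
        med = [np.median(values[raw_labels == k]) for k in (0, 1)]
        if np.isnan(med).any():
            raise ValueError("degenerate partition: one group is empty")
        proximal_k = int(np.argmin(med))
        labels = (raw_labels != proximal_k).astype(int)  # 0 = proximal, 1 = distal
        self.labels_ = labels
        self.median_proximal_ = float(med[proximal_k])
        self.median_distal_ = float(med[1 - proximal_k])
        if not self.median_proximal_ < self.median_distal_:
            raise ValueError("degenerate partition: group medians not separated")
        order = [proximal_k, 1 - proximal_k]
        self.cluster_centers_ = km.cluster_centers_[order]
        self.n_iter_ = km.n_iter_
        if not 0.0 < self.exclusion < 1.0:
            raise ValueError("exclusion must be in (0, 1)")
        distal = values[labels == 1]
        self.threshold_ = float(np.quantile(distal, 1.0 - self.exclusion))
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class KataegisDetector(BaseEstimator):
    """End-to-end kataegis detection on a mutation catalog.

    fit(catalog) computes IMDs, partitions them, derives the calling
    threshold (unless ``threshold`` is given explicitly, e.g. a threshold
    set on a reference genotype's pooled IMDs) and calls clusters of at
    least ``min_mutations`` adjacent mutations with all gaps strictly
    below the threshold.

    Attributes
    ----------
    imds_ : IMDSeries
    partition_ : IMDPartition or None (None when ``threshold`` was given)
    threshold_ : float
    clusters_ : list of ClusterCall
    labels_ : ndarray
        Per catalog record: cluster index, or -1 for unclustered.
    """

    def __init__(
        self,
        exclusion: float = 0.99,
        min_mutations: int = 5,
        threshold: float | None = None,
    ):
        self.exclusion = exclusion
        self.min_mutations = min_mutations
        self.threshold = threshold

    def fit(self, catalog: MutationCatalog, y=None):
        from . import detection

        if not isinstance(catalog, MutationCatalog):
            raise TypeError("KataegisDetector.fit expects a MutationCatalog")
        catalog.validate()
        self.imds_ = detection.compute_imds(catalog)
        if self.threshold is not None:
            self.partition_ = None
            self.threshold_ = float(self.threshold)
        else:
            if len(self.imds_) < 4:
                raise ValueError(
                    "insufficient IMDs to derive a threshold "
                    f"({len(self.imds_)} entries; need >= 4). Provide a "
                    "threshold explicitly or pool more clones."
                )
            self.partition_ = detection.partition_imds(self.imds_)
            self.threshold_ = detection.derive_threshold(
                self.partition_, self.exclusion
            )
        self.clusters_ = detection.call_clusters(
            catalog, self.threshold_, self.min_mutations
        )
        self.labels_ = detection.cluster_labels(catalog, self.clusters_)
        return self

    def fit_predict(self, catalog: MutationCatalog, y=None):
        return self.fit(catalog).labels_
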