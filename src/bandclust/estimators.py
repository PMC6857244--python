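"""scikit-learn style estimator for adjacency-constrained Ward clustering."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .band import BandSimilarity
from .engine import _agglomerate
from .model_selection import select_broken_stick, select_slope_heuristic


class AdjacencyConstrainedWard(ClusterMixin, BaseEstimator):
    """Adjacency-constrained Ward clustering of a precomputed similarity.

    Hierarchical agglomerative clustering in which only clusters that
    are adjacent in the object ordering may merge, so every cluster is
    a contiguous interval (an LD block, a TAD, ...).  Ward linkages are
    evaluated in O(1) from precomputed pencil sums and candidate
    fusions live in a lazy min-heap, giving O(p(h + log p)) time and
    O(ph) memory for bandwidth ``h``.

    Parameters
    ----------
    n_clusters : int, optional
        Cut the hierarchy at this many clusters.  Mutually exclusive
        with ``select``.
    bandwidth : int, optional
        Band bandwidth ``h``: similarities of pairs more than
        ``h - 1`` apart are treated as 0.  Defaults to ``p`` (no
        approximation).  Ignored when ``X`` is already a
        :class:`~bandclust.BandSimilarity`.
    select : {"broken-stick", "slope"}, optional
        Data-driven choice of the cluster count.  The default (when
        ``n_clusters`` is also None) is the broken-stick rule.
    k_max : int, optional
        Search bound for the slope heuristic.
    strict_band : bool, default False
        Raise if a dense input has nonzero entries outside the band
        instead of dropping them.

    Attributes
    ----------
    dendrogram_ : Dendrogram
        The full hierarchy (p - 1 merges with Ward heights).
    labels_ : ndarray of shape (p,)
        Contiguous cluster labels ``1..K``.
    n_clusters_ : int
        The cluster count actually used.
    heights_ : ndarray of shape (p - 1,)
        Ward linkage value of each merge.
    selection_ : ClusterSelection or None
        Criterion trace when a selection method was used.

    Examples
    --------
    >>> import numpy as np
    >>> from bandclust import AdjacencyConstrainedWard
    >>> S = np.kron(np.eye(2), np.ones((3, 3)))
    >>> model = AdjacencyConstrainedWard(n_clusters=2).fit(S)
    >>> model.labels_
    array([1, 1, 1, 2, 2, 2])
    """

    def __init__(self, n_clusters=None, *, bandwidth=None, select=None,
                 k_max=None, strict_band=False):
        self.n_clusters = n_clusters
        self.bandwidth = bandwidth
        self.select = select
        self.k_max = k_max
        self.strict_band = strict_band

    def fit(self, X, y=None):
        """Cluster a precomputed similarity.

        ``X`` is either a symmetric ``(p, p)`` similarity matrix or a
        :class:`~bandclust.BandSimilarity`.
        """
        if self.n_clusters is not None and self.select is not None:
            raise ValueError("n_clusters and select are mutually exclusive")
        if self.select not in (None, "broken-stick", "slope"):
            raise ValueError(f"unknown select method: {self.select!r}")
        if isinstance(X, BandSimilarity):
            B = X
        else:
            X = np.asarray(X, dtype=float)
            B = BandSimilarity.from_dense(
                X, h=self.bandwidth, strict=self.strict_band
            )
        self.n_leaves_ = B.p
        self.bandwidth_ = B.h
        self.dendrogram_ = _agglomerate(B)
        self.heights_ = self.dendrogram_.height
        self.selection_ = None
        if self.n_clusters is not None:
            if not (1 <= self.n_clusters <= B.p):
                raise ValueError(f"need 1 <= n_clusters <= p={B.p}")
            self.n_clusters_ = int(self.n_clusters)
            self.labels_ = self.dendrogram_.cut(self.n_clusters_)
        else:
            if self.select == "slope":
                sel = select_slope_heuristic(self.dendrogram_,
                                             k_max=self.k_max)
            else:
                sel = select_broken_stick(self.dendrogram_)
            self.selection_ = sel
            self.n_clusters_ = sel.n_clusters
            self.labels_ = sel.labels
        return self

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.pairwise = True
        return tags
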