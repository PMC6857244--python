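"""Adjacency-constrained hierarchical agglomerative clustering engine.

Only clusters that are adjacent in the object ordering may merge, so
every cluster is a contiguous interval and the full hierarchy is a
sequence of ``p - 1`` recorded merges.  Two implementations are
provided:

* :func:`cluster` — the quasi-linear algorithm: Ward linkages in O(1)
  from precomputed pencil sums, candidate fusions in a lazy min-heap;
  O(p(h + log p)) time, O(ph) memory.
* :func:`naive_cluster` — the quadratic reference that recomputes every
  candidate linkage from scratch by direct summation over the dense
  matrix.  It exists as an independent oracle and for tiny problems.

Both use the same deterministic tie-break (smallest left boundary
wins among equal linkages) and produce identical output.

Recorded heights are raw Ward linkages.  With a general (non
positive-semidefinite) similarity they may decrease between successive
merges ("reversals"); the dendrogram keeps the raw values, flags
non-monotonicity, and a warning is logged when any height is negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .band import BandSimilarity
from .heap import CandidateFusion, FusionHeap
from .pencils import PencilSums

logger = logging.getLogger(__name__)


@dataclass
class MergeStep:
    """One merge: adjacent intervals ``[i, m)`` and ``[m, j)`` fuse."""

    step: int        # 1..p-1
    left_ref: int    # negative 1-based leaf index, or earlier step number
    right_ref: int
    start: int       # i
    mid: int         # m
    end: int         # j
    height: float    # Ward linkage delta of this merge
    size_left: int
    size_right: int


@dataclass
class Dendrogram:
    """The ``p - 1`` recorded merges of a constrained hierarchy.

    Merge references follow the common agglomerative merge-table
    convention: leaves are the negated 1-based object indices, internal
    nodes are positive step numbers.
    """

    p: int
    left_ref: np.ndarray
    right_ref: np.ndarray
    start: np.ndarray
    mid: np.ndarray
    end: np.ndarray
    height: np.ndarray
    labels: list | None = field(default=None, repr=False)

    def __post_init__(self):
        n = self.p - 1
        for name in ("left_ref", "right_ref", "start", "mid", "end"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length p - 1 = {n}")
            setattr(self, name, arr)
        self.height = np.asarray(self.height, dtype=float)
        if self.height.shape != (n,):
            raise ValueError("height must have length p - 1")

    @property
    def n_merges(self) -> int:
        return self.p - 1

    @property
    def monotone(self) -> bool:
        """True iff heights never decrease (no reversals)."""
        return bool(np.all(np.diff(self.height) >= 0))

    @property
    def sizes(self) -> np.ndarray:
        return self.end - self.start

    def steps(self):
        """Iterate over :class:`MergeStep` records."""
        for t in range(self.n_merges):
            yield MergeStep(
                t + 1, int(self.left_ref[t]), int(self.right_ref[t]),
                int(self.start[t]), int(self.mid[t]), int(self.end[t]),
                float(self.height[t]),
                int(self.mid[t] - self.start[t]),
                int(self.end[t] - self.mid[t]),
            )

    # ------------------------------------------------------------------

    def cut(self, K: int) -> np.ndarray:
        """Labels of the ``K``-cluster partition (undo the last K-1 merges).

        Labels are contiguous blocks numbered ``1..K`` left to right.
        """
        if not (1 <= K <= self.p):
            raise ValueError(f"need 1 <= K <= p, got K={K}")
        kept = self.mid[: self.p - K]  # interior boundaries removed
        boundaries = np.setdiff1d(np.arange(1, self.p), kept)
        return np.searchsorted(boundaries, np.arange(self.p),
                               side="right").astype(np.int64) + 1

    def to_table(self) -> pd.DataFrame:
        """Merge table as a DataFrame (TSV-friendly)."""
        return pd.DataFrame({
            "step": np.arange(1, self.p),
            "left_ref": self.left_ref,
            "right_ref": self.right_ref,
            "start": self.start,
            "mid": self.mid,
            "end": self.end,
            "height": self.height,
            "size": self.sizes,
        })

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "Dendrogram":
        """Inverse of :meth:`to_table`."""
        return cls(
            p=len(df) + 1,
            left_ref=df["left_ref"].to_numpy(),
            right_ref=df["right_ref"].to_numpy(),
            start=df["start"].to_numpy(),
            mid=df["mid"].to_numpy(),
            end=df["end"].to_numpy(),
            height=df["height"].to_numpy(),
        )

    def to_scipy_linkage(self) -> np.ndarray:
        """Linkage matrix in the scipy ``(p-1, 4)`` convention."""
        Z = np.zeros((self.p - 1, 4))
        for t in range(self.p - 1):
            Z[t, 0] = -self.left_ref[t] - 1 if self.left_ref[t] < 0 \
                else self.p + self.left_ref[t] - 1
            Z[t, 1] = -self.right_ref[t] - 1 if self.right_ref[t] < 0 \
                else self.p + self.right_ref[t] - 1
            Z[t, 2] = self.height[t]
            Z[t, 3] = self.end[t] - self.start[t]
        return Z

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights.

        A child's branch length is the parent height minus the child
        height (0 for leaves); negative lengths arising from reversals
        are clamped to 0 with a warning.
        """
        labels = self.labels or [f"L{i + 1}" for i in range(self.p)]
        node_height = {}
        newick = {}
        for i in range(self.p):
            newick[-(i + 1)] = str(labels[i])
            node_height[-(i + 1)] = 0.0
        clamped = 0
        for t in range(self.p - 1):
            parts = []
            for ref in (int(self.left_ref[t]), int(self.right_ref[t])):
                bl = self.height[t] - node_height[ref]
                if bl < 0:
                    clamped += 1
                    bl = 0.0
                parts.append(f"{newick.pop(ref)}:{bl:.10g}")
            ref = t + 1
            newick[ref] = f"({parts[0]},{parts[1]})"
            node_height[ref] = float(self.height[t])
        if clamped:
            logger.warning(
                "clamped %d negative branch length(s) to 0 in Newick export",
                clamped,
            )
        return newick[self.p - 1] + ";"


def first_difference_index(d1: Dendrogram, d2: Dendrogram) -> float:
    """Fraction ``t/(p-1)`` of leading merges on which two hierarchies agree.

    ``t`` counts the leading merge steps whose (left interval, right
    interval) pairs coincide — heights are ignored.  The score is 0 when
    the very first fusions differ and 1 when the dendrograms are
    identical.
    """
    if d1.p != d2.p:
        raise ValueError("dendrograms must cluster the same number of objects")
    same = ((d1.start == d2.start) & (d1.mid == d2.mid)
            & (d1.end == d2.end))
    t = int(np.argmin(same)) if not same.all() else d1.n_merges
    return t / (d1.p - 1)


# ----------------------------------------------------------------------
# quasi-linear engine
# ----------------------------------------------------------------------

def _agglomerate(B: BandSimilarity, check: bool = False) -> Dendrogram:
    p = B.p
    if p < 2:
        raise ValueError("need at least 2 objects to cluster")
    P = PencilSums.from_band(B)
    ward = P.ward_linkage

    fusions = [
        CandidateFusion(
            id=t, left_start=t, mid=t + 1, right_end=t + 2,
            linkage=ward(t, t + 1, t + 2),
            prev_id=t - 1 if t > 0 else None,
            next_id=t + 1 if t < p - 2 else None,
        )
        for t in range(p - 1)
    ]
    H = FusionHeap.build(fusions)
    store = H.store
    next_id = p - 1

    ref = {i: -(i + 1) for i in range(p)}  # cluster start -> merge ref
    left_ref = np.empty(p - 1, dtype=np.int64)
    right_ref = np.empty(p - 1, dtype=np.int64)
    start = np.empty(p - 1, dtype=np.int64)
    mid = np.empty(p - 1, dtype=np.int64)
    end = np.empty(p - 1, dtype=np.int64)
    height = np.empty(p - 1)

    for step in range(1, p):
        f = H.pop_min_active()
        i, m, j = f.left_start, f.mid, f.right_end
        t = step - 1
        left_ref[t], right_ref[t] = ref[i], ref[m]
        start[t], mid[t], end[t] = i, m, j
        height[t] = f.linkage
        ref[i] = step
        del ref[m]

        pl = store[f.prev_id] if f.prev_id is not None else None
        nx = store[f.next_id] if f.next_id is not None else None
        if pl is not None:
            H.invalidate(pl.id)
        if nx is not None:
            H.invalidate(nx.id)

        new_left = new_right = None
        if pl is not None:
            new_left = CandidateFusion(
                id=next_id, left_start=pl.left_start, mid=i, right_end=j,
                linkage=ward(pl.left_start, i, j), prev_id=pl.prev_id,
            )
            next_id += 1
        if nx is not None:
            # at the chromosome ends only one new fusion is defined
            new_right = CandidateFusion(
                id=next_id, left_start=i, mid=j, right_end=nx.right_end,
                linkage=ward(i, j, nx.right_end), next_id=nx.next_id,
            )
            next_id += 1
        if new_left is not None and new_right is not None:
            new_left.next_id = new_right.id
            new_right.prev_id = new_left.id
        elif new_left is not None:
            new_left.next_id = None
        elif new_right is not None:
            new_right.prev_id = None
        if new_left is not None:
            if new_left.prev_id is not None:
                store[new_left.prev_id].next_id = new_left.id
            H.insert(new_left)
        if new_right is not None:
            if new_right.next_id is not None:
                store[new_right.next_id].prev_id = new_right.id
            H.insert(new_right)

        if check:
            _check_partition(H, p, step)

    if np.any(height < 0):
        logger.warning(
            "similarity is not positive semidefinite: %d negative "
            "linkage height(s) recorded", int(np.sum(height < 0)),
        )
    dg = Dendrogram(p=p, left_ref=left_ref, right_ref=right_ref,
                    start=start, mid=mid, end=end, height=height,
                    labels=B.labels)
    dg._n_lazy_deletions = H.n_lazy_deletions  # diagnostic, bounded by 2p
    return dg


def _check_partition(H: FusionHeap, p: int, step: int) -> None:
    """Active fusions must chain into a contiguous partition of [0, p)."""
    active = [f for f in H.store.values() if f.valid]
    if step == p - 1:
        assert not active
        return
    for f in active:
        assert f.left_start < f.mid < f.right_end
    first = [f for f in active
             if f.prev_id is None or not H.store[f.prev_id].valid]
    assert len(first) == 1, "linked list must have a unique head"
    f = first[0]
    seen = 1
    while f.next_id is not None:
        g = H.store[f.next_id]
        assert g.valid and g.left_start == f.mid and g.mid == f.right_end
        f = g
        seen += 1
    assert seen == len(active)
    # p - step clusters remain after `step` merges
    assert seen == p - step - 1


def cluster(B: BandSimilarity) -> Dendrogram:
    """Adjacency-constrained Ward HAC of a band similarity.

    Quasi-linear algorithm: O(p(h + log p)) time, O(ph) memory.
    """
    return _agglomerate(B)


# ----------------------------------------------------------------------
# quadratic reference (independent oracle)
# ----------------------------------------------------------------------

def naive_cluster(M, labels=None) -> Dendrogram:
    """Quadratic reference: every linkage from scratch by direct sums.

    ``M`` is a dense symmetric similarity matrix.  Same tie-break as
    :func:`cluster`; on any input the two agree exactly.
    """
    if isinstance(M, BandSimilarity):
        labels = labels if labels is not None else M.labels
        M = M.to_dense()
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("similarity matrix must be square")
    if np.max(np.abs(M - M.T), initial=0.0) > 1e-8:
        raise ValueError("similarity matrix must be symmetric")
    p = M.shape[0]
    if p < 2:
        raise ValueError("need at least 2 objects to cluster")

    def linkage(i, m, j):
        sl = M[i:m, i:m].sum()
        sr = M[m:j, m:j].sum()
        su = M[i:j, i:j].sum()
        return sl / (m - i) + sr / (j - m) - su / (j - i)

    bounds = list(range(p + 1))
    ref = {i: -(i + 1) for i in range(p)}
    rows = []
    for step in range(1, p):
        best_key, best_idx = None, None
        for idx in range(len(bounds) - 2):
            i, m, j = bounds[idx], bounds[idx + 1], bounds[idx + 2]
            key = (linkage(i, m, j), i)
            if best_key is None or key < best_key:
                best_key, best_idx = key, idx
        i, m, j = (bounds[best_idx], bounds[best_idx + 1],
                   bounds[best_idx + 2])
        rows.append((ref[i], ref[m], i, m, j, best_key[0]))
        ref[i] = step
        del ref[m]
        del bounds[best_idx + 1]
    lr, rr, st, md, en, ht = map(np.array, zip(*rows))
    return Dendrogram(p=p, left_ref=lr, right_ref=rr, start=st, mid=md,
                      end=en, height=ht, labels=labels)
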