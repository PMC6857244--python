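"""Min-heap of candidate fusions with a side array and lazy invalidation.

The agglomeration engine needs three operations per merge step: find
the best (smallest-linkage) candidate fusion, insert up to two new
candidates, and retire the up-to-two neighbors of the merged pair.  A
binary min-heap gives O(log p) find-min/insert; retirement is *lazy*:
the record's validity flag is flipped in O(1) and stale heap roots are
discarded when they surface.  Over a full clustering run at most 2p
roots are ever discarded this way.

The heap itself stores only ``(linkage, left_start, id)`` keys; all
mutable candidate state (cluster intervals, the doubly linked list of
fusions in chromosome order, validity) lives in a dedicated side store
addressed by id.  Ties on the linkage value are broken toward the
fusion with the smaller left-boundary index, which makes the whole
algorithm deterministic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field


class EmptyHeapError(Exception):
    """Raised when no active candidate fusion remains."""


@dataclass
class CandidateFusion:
    """A possible merge of the adjacent clusters ``[i, m)`` and ``[m, j)``.

    ``prev_id``/``next_id`` link the candidate fusions in chromosome
    order (``None`` at the chromosome ends).
    """

    id: int
    left_start: int   # i
    mid: int          # m: left.end == right.start (adjacency)
    right_end: int    # j
    linkage: float
    prev_id: int | None = None
    next_id: int | None = None
    valid: bool = field(default=True)

    @property
    def key(self) -> tuple[float, int, int]:
        return (self.linkage, self.left_start, self.id)


class FusionHeap:
    """Binary min-heap over :class:`CandidateFusion` records."""

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, int]] = []
        self.store: dict[int, CandidateFusion] = {}
        #: stale roots discarded so far (bounded by 2p over a full run)
        self.n_lazy_deletions = 0

    @classmethod
    def build(cls, fusions) -> "FusionHeap":
        """Heapify a list of candidate fusions in O(n)."""
        H = cls()
        for f in fusions:
            if f.id in H.store:
                raise ValueError(f"duplicate fusion id {f.id}")
            H.store[f.id] = f
        H._heap = [f.key for f in H.store.values()]
        heapq.heapify(H._heap)
        return H

    def __len__(self) -> int:
        return sum(1 for f in self.store.values() if f.valid)

    def insert(self, f: CandidateFusion) -> None:
        """Push a fresh candidate fusion, O(log n)."""
        if f.id in self.store:
            raise ValueError(f"fusion id {f.id} already present")
        self.store[f.id] = f
        heapq.heappush(self._heap, f.key)

    def invalidate(self, fusion_id: int) -> None:
        """Flag a fusion inactive in O(1); the heap array is untouched."""
        try:
            self.store[fusion_id].valid = False
        except KeyError:
            raise KeyError(f"unknown fusion id {fusion_id}") from None

    def pop_min_active(self) -> CandidateFusion:
        """Return and consume the active fusion with the smallest key.

        Inactive roots encountered on the way are discarded (lazy
        deletion).  Raises :class:`EmptyHeapError` when no active fusion
        remains.
        """
        while self._heap:
            key = heapq.heappop(self._heap)
            f = self.store[key[2]]
            if not f.valid:
                self.n_lazy_deletions += 1
                continue
            f.valid = False  # consumed
            return f
        raise EmptyHeapError("no active candidate fusion")
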