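"""Pencil cumulative sums: O(1) interval sums and Ward linkages.

For a banded similarity the sum of all entries inside any contiguous
cluster ``C = [i, j)`` can be written with three precomputed
"pencil"-shaped partial sums.  The forward pencil

    Pfwd(r, l) = sum of s_ab over 0 <= a, b < r with |a - b| < l

covers the first ``l`` sub/superdiagonals of the leading ``r x r``
block; the backward pencil is the same quantity on the trailing block.
With ``l = min(h, k)`` and ``k = j - i``,

    S(C) = Pfwd(j, l) + Pbwd(i, l) - Pfwd(p, l),

because pairs straddling the interval either violate ``|a - b| < l``
(when ``k <= h``) or lie outside the band (when ``k > h``).  Ward's
linkage between adjacent clusters then follows from the kernel-trick
identity

    delta(C, C') = S(C)/|C| + S(C')/|C'| - S(C u C')/|C u C'|

in O(1) arithmetic.  Precomputing all pencils costs O(ph) time and
space: 2ph meaningful values.
"""

from __future__ import annotations

import numpy as np

from .band import BandSimilarity


def _forward_table(band: np.ndarray) -> np.ndarray:
    """Forward pencil table of shape (p+1, h); row r covers indices < r.

    Row recursion: the leading-block pencil grows by the new row's
    diagonal entry plus twice its in-band left neighbors within the
    pencil width.
    """
    p, h = band.shape
    # T[r, d] = s_{r-d, r} (0 when r - d < 0)
    T = np.zeros((p, h))
    for d in range(h):
        T[d:, d] = band[: p - d, d]
    # row contribution at width l: s_rr + 2 * sum_{d=1}^{l-1} s_{r-d, r}
    C = 2.0 * np.cumsum(T, axis=1) - band[:, [0]]
    out = np.zeros((p + 1, h))
    np.cumsum(C, axis=0, out=out[1:])
    return out


def _reverse_band(band: np.ndarray) -> np.ndarray:
    """Band table of the similarity with the object order reversed."""
    p, h = band.shape
    rev = np.zeros_like(band)
    for d in range(h):
        rev[: p - d, d] = band[: p - d, d][::-1]
    return rev


class PencilSums:
    """Precomputed forward/backward pencils for a :class:`BandSimilarity`.

    Tables are stored as ``(p+1, h)`` arrays with an all-zero padding
    row (``r = 0`` forward, ``r = p`` backward) so interval queries need
    no branches; the ``2ph`` meaningful entries are reported by
    :attr:`n_pencils`.
    """

    def __init__(self, forward: np.ndarray, backward: np.ndarray):
        self.forward = forward
        self.backward = backward
        self.p = forward.shape[0] - 1
        self.h = forward.shape[1]

    @classmethod
    def from_band(cls, B: BandSimilarity) -> "PencilSums":
        """Fill both tables by cumulative-sum recursions in O(ph)."""
        fwd = _forward_table(B.band)
        fwd_rev = _forward_table(_reverse_band(B.band))
        # Pbwd(r, .) covers indices >= r  ==  forward pencil of the
        # reversed ordering at boundary p - r
        bwd = fwd_rev[::-1].copy()
        return cls(fwd, bwd)

    @property
    def n_pencils(self) -> int:
        """Number of stored pencil values (excludes padding rows)."""
        return 2 * self.p * self.h

    @property
    def full(self) -> np.ndarray:
        """Full pencils ``Pfwd(p, l)`` for ``l = 1..h``."""
        return self.forward[self.p]

    def interval_sum(self, i: int, j: int) -> float:
        """``S(C)`` for the contiguous cluster ``C = [i, j)``, O(1)."""
        if not (0 <= i < j <= self.p):
            raise ValueError(f"invalid interval [{i}, {j})")
        l = min(self.h, j - i) - 1
        return float(self.forward[j, l] + self.backward[i, l]
                     - self.forward[self.p, l])

    def ward_linkage(self, i: int, m: int, j: int) -> float:
        """Ward linkage between adjacent clusters ``[i, m)`` and ``[m, j)``."""
        if not (0 <= i < m < j <= self.p):
            raise ValueError(f"invalid split {i} < {m} < {j}")
        sl = self.interval_sum(i, m)
        sr = self.interval_sum(m, j)
        su = self.interval_sum(i, j)
        return sl / (m - i) + sr / (j - m) - su / (j - i)
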