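"""Band similarity matrices.

A similarity between ``p`` linearly ordered objects (SNPs along a
chromosome, Hi-C bins, stratigraphic samples, ...) is *banded* with
bandwidth ``h`` when ``s_ij = 0`` for ``|i - j| >= h``.  Under this
assumption only the main diagonal and the ``h - 1`` superdiagonals need
to be stored, which is what :class:`BandSimilarity` does.  ``h = p``
imposes no restriction and recovers a full dense symmetric matrix.

Indexing is 0-based half-open throughout the library; 1-based indices
appear only at the file I/O boundary (MatrixMarket-style triplets).
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

#: absolute tolerance for the symmetry check of dense inputs
ASYMMETRY_TOL = 1e-8


class BandSimilarity:
    """Symmetric similarity restricted to a diagonal band.

    Parameters
    ----------
    band : ndarray of shape (p, h)
        ``band[i, d]`` holds ``s_{i, i+d}``; column 0 is the main
        diagonal.  Entries with ``i + d >= p`` fall outside the matrix
        and must be 0.
    labels : sequence of str, optional
        Object names (e.g. SNP identifiers).
    positions : sequence of int, optional
        Genomic coordinates (base pairs), one per object.

    The symmetric completion is implied: ``get(i, j)`` with ``j < i``
    returns ``s_ji``, and pairs with ``|i - j| >= h`` return exactly 0.
    """

    def __init__(self, band, labels=None, positions=None):
        band = np.array(band, dtype=float)
        if band.ndim != 2:
            raise ValueError("band must be a 2-d array of shape (p, h)")
        p, h = band.shape
        if p < 1 or h < 1 or h > p:
            raise ValueError(f"need 1 <= h <= p, got p={p}, h={h}")
        if not np.all(np.isfinite(band)):
            raise ValueError("band values must be finite")
        # entries past the right edge of the matrix must vanish
        for d in range(1, h):
            if d > 0 and np.any(band[p - d:, d] != 0):
                raise ValueError(
                    "band entries beyond the matrix edge must be zero"
                )
        self.band = band
        self.labels = None if labels is None else list(labels)
        if self.labels is not None and len(self.labels) != p:
            raise ValueError("labels length must equal p")
        self.positions = None
        if positions is not None:
            positions = np.asarray(positions, dtype=np.int64)
            if positions.shape != (p,):
                raise ValueError("positions length must equal p")
            self.positions = positions

    @property
    def p(self) -> int:
        """Number of ordered objects."""
        return self.band.shape[0]

    @property
    def h(self) -> int:
        """Bandwidth: pairs with ``|i - j| >= h`` have similarity 0."""
        return self.band.shape[1]

    def get(self, i: int, j: int) -> float:
        """Similarity ``s_ij`` (symmetric completion, 0 outside band)."""
        if not (0 <= i < self.p and 0 <= j < self.p):
            raise IndexError(f"index out of range: ({i}, {j})")
        if j < i:
            i, j = j, i
        d = j - i
        if d >= self.h:
            return 0.0
        return float(self.band[i, d])

    def to_dense(self) -> np.ndarray:
        """Materialize the full symmetric ``p x p`` matrix."""
        p, h = self.p, self.h
        M = np.zeros((p, p))
        for d in range(h):
            idx = np.arange(p - d)
            M[idx, idx + d] = self.band[: p - d, d]
            M[idx + d, idx] = self.band[: p - d, d]
        return M

    def shift_diagonal(self, lam: float) -> "BandSimilarity":
        """Return a copy with ``s_ii + lam`` on the diagonal.

        By Miyamoto's shift theorem the Ward hierarchy of the shifted
        similarity is identical, with every linkage value moved by
        exactly ``+lam``; the shift is how a non-positive-definite
        similarity can be reasoned about as a kernel.
        """
        if not np.isfinite(lam):
            raise ValueError("shift must be finite")
        band = self.band.copy()
        band[:, 0] += lam
        return BandSimilarity(band, labels=self.labels,
                              positions=self.positions)

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------

    @classmethod
    def from_dense(cls, M, h=None, strict=False, labels=None,
                   positions=None) -> "BandSimilarity":
        """Extract the first ``h`` diagonals of a dense symmetric matrix.

        With ``strict=True`` any nonzero entry outside the band raises;
        otherwise such entries are silently dropped (``h = p`` keeps
        everything).
        """
        M = np.asarray(M, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("similarity matrix must be square")
        p = M.shape[0]
        if not np.all(np.isfinite(M)):
            raise ValueError("similarity matrix must be finite")
        if np.max(np.abs(M - M.T), initial=0.0) > ASYMMETRY_TOL:
            raise ValueError(
                f"matrix is asymmetric beyond tolerance {ASYMMETRY_TOL}"
            )
        M = 0.5 * (M + M.T)
        if h is None:
            h = p
        if not (1 <= h <= p):
            raise ValueError(f"need 1 <= h <= p, got h={h}, p={p}")
        if strict and h < p:
            iu, ju = np.triu_indices(p, k=h)
            if np.any(M[iu, ju] != 0):
                raise ValueError(
                    f"nonzero entries outside bandwidth {h} with strict=True"
                )
        band = np.zeros((p, h))
        for d in range(h):
            band[: p - d, d] = np.diagonal(M, offset=d)
        return cls(band, labels=labels, positions=positions)

    @classmethod
    def from_triplets(cls, entries, p, h, labels=None,
                      positions=None) -> "BandSimilarity":
        """Build from sparse ``(i, j, value)`` triplets, 1-based indices.

        Unspecified in-band entries default to 0.  ``(i, j)`` and
        ``(j, i)`` may both appear only with equal values; duplicate
        pairs with conflicting values raise.  A missing diagonal entry
        defaults to 0 with a logged warning (Hi-C maps often omit
        self-contacts).  Out-of-band entries are dropped with a logged
        count.
        """
        if not (1 <= h <= p):
            raise ValueError(f"need 1 <= h <= p, got h={h}, p={p}")
        band = np.zeros((p, h))
        seen: dict[tuple[int, int], float] = {}
        n_dropped = 0
        for i, j, v in entries:
            i, j = int(i), int(j)
            v = float(v)
            if not (1 <= i <= p and 1 <= j <= p):
                raise ValueError(f"triplet index out of range: ({i}, {j})")
            if not np.isfinite(v):
                raise ValueError(f"non-finite value at ({i}, {j})")
            a, b = (i - 1, j - 1) if i <= j else (j - 1, i - 1)
            key = (a, b)
            if key in seen:
                if seen[key] != v:
                    raise ValueError(
                        f"conflicting duplicate entry at ({i}, {j}): "
                        f"{seen[key]} vs {v}"
                    )
                continue
            seen[key] = v
            d = b - a
            if d >= h:
                n_dropped += 1
                continue
            band[a, d] = v
        if n_dropped:
            logger.warning("dropped %d out-of-band triplet(s)", n_dropped)
        n_missing_diag = p - sum(1 for (a, b) in seen if a == b)
        if n_missing_diag:
            logger.warning(
                "%d diagonal entr(ies) missing from triplets; defaulting to 0",
                n_missing_diag,
            )
        return cls(band, labels=labels, positions=positions)

    @classmethod
    def from_dissimilarity(cls, D, labels=None,
                           positions=None) -> "BandSimilarity":
        """Convert a dissimilarity matrix to a (full-bandwidth) similarity.

        Uses ``s_ij = (c - d_ij**2) / 2`` with ``c = max d_ij**2``.  A
        uniform additive shift of all similarities leaves every Ward
        linkage unchanged, so the resulting hierarchy does not depend on
        the choice of ``c``; for Euclidean distances the hierarchy is
        exactly classical (adjacency-constrained) Ward.

        Only full bandwidth is supported: out-of-band pairs are
        hard-coded to similarity 0, which is incompatible with the
        additive constant ``c``.
        """
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.all(np.isfinite(D)):
            raise ValueError("dissimilarity matrix must be finite")
        if np.max(np.abs(D - D.T), initial=0.0) > ASYMMETRY_TOL:
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(D < 0):
            raise ValueError("dissimilarities must be nonnegative")
        if np.any(np.diagonal(D) != 0):
            raise ValueError("dissimilarity diagonal must be zero")
        D2 = (0.5 * (D + D.T)) ** 2
        c = float(D2.max(initial=0.0))
        S = 0.5 * (c - D2)
        return cls.from_dense(S, h=D.shape[0], labels=labels,
                              positions=positions)

    def __repr__(self) -> str:  # pragma: no cover
        return f"BandSimilarity(p={self.p}, h={self.h})"
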