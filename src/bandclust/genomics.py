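"""Genomics adapters: LD and Hi-C similarities, BED export, bandwidth choice.

Two data sources map naturally onto banded similarities:

* **SNP genotypes** — linkage disequilibrium measured as the squared
  Pearson correlation ``r^2`` between allele-dosage vectors.  Physical
  linkage decays with genomic distance, so restricting ``r^2`` to SNP
  pairs less than ``h`` apart loses almost nothing while shrinking the
  problem from p^2 to p*h.  The r^2 similarity is a kernel, so the
  resulting Ward hierarchy has a proper pseudo-inertia interpretation;
  the contiguous clusters are LD blocks (haplotype blocks).
* **Hi-C contact maps** — raw intra-chromosomal contact counts,
  log-transformed to tame the skew; the contiguous clusters are
  TAD-like domains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .band import BandSimilarity
from .engine import cluster, first_difference_index

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Unphased dosages: ``n`` individuals by ``p`` ordered SNPs.

    ``dosages`` holds values in {0, 1, 2} with NaN for missing calls.
    ``positions`` (base pairs, 1-based) must be strictly increasing.
    """

    dosages: np.ndarray
    positions: np.ndarray | None = None
    snp_ids: list | None = None
    chromosome: str = "chr1"

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-d (individuals x SNPs)")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.shape != (self.p,):
                raise ValueError("positions length must equal p")
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]


@dataclass
class ContactMap:
    """Intra-chromosomal Hi-C contacts as sparse bin-pair counts.

    ``triplets`` is an ``(m, 3)`` array of ``(bin_i, bin_j, count)``
    with 0-based bins and nonnegative integer counts.
    """

    p: int
    triplets: np.ndarray
    bin_size: int = 40_000
    chromosome: str = "chr1"

    def __post_init__(self):
        self.triplets = np.asarray(self.triplets, dtype=np.int64)
        if self.triplets.size == 0:
            self.triplets = self.triplets.reshape(0, 3)
        if self.triplets.ndim != 2 or self.triplets.shape[1] != 3:
            raise ValueError("triplets must have shape (m, 3)")
        if np.any(self.triplets[:, 2] < 0):
            raise ValueError("contact counts must be nonnegative")
        bins = self.triplets[:, :2]
        if bins.size and (bins.min() < 0 or bins.max() >= self.p):
            raise ValueError("bin index out of range")


def ld_band(G: GenotypeMatrix, h: int) -> BandSimilarity:
    """Banded LD similarity: ``s_ij = r^2`` for SNP pairs ``|i - j| < h``.

    ``r^2`` is the squared Pearson correlation of the unphased dosage
    vectors (composite LD), computed over pairwise-complete
    individuals.  The diagonal is 1.  Pairs where either SNP is
    monomorphic (or too few complete pairs remain) get similarity 0;
    their count is logged.
    """
    if G.n < 2:
        raise ValueError("need at least 2 individuals")
    if G.p < 2:
        raise ValueError("need at least 2 SNPs")
    X = G.dosages
    p = G.p
    if not (1 <= h <= p):
        raise ValueError(f"need 1 <= h <= p, got h={h}")
    finite = np.isfinite(X)
    if not np.any(finite.any(axis=0)):
        raise ValueError("all genotypes missing")
    band = np.zeros((p, h))
    band[:, 0] = 1.0
    n_degenerate = 0
    for d in range(1, h):
        X1, X2 = X[:, : p - d], X[:, d:]
        m = finite[:, : p - d] & finite[:, d:]
        A1 = np.where(m, X1, 0.0)
        A2 = np.where(m, X2, 0.0)
        n = m.sum(axis=0).astype(float)
        s1 = A1.sum(axis=0)
        s2 = A2.sum(axis=0)
        s11 = (A1 * A1).sum(axis=0)
        s22 = (A2 * A2).sum(axis=0)
        s12 = (A1 * A2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = n * s12 - s1 * s2
            v1 = n * s11 - s1 * s1
            v2 = n * s22 - s2 * s2
            r2 = (cov * cov) / (v1 * v2)
        bad = (n < 2) | (v1 <= 0) | (v2 <= 0) | ~np.isfinite(r2)
        n_degenerate += int(bad.sum())
        r2[bad] = 0.0
        band[: p - d, d] = r2
    if n_degenerate:
        logger.info(
            "%d SNP pair(s) monomorphic/all-missing; r^2 set to 0",
            n_degenerate,
        )
    return BandSimilarity(band, labels=G.snp_ids, positions=G.positions)


def hic_band(C: ContactMap, h: int) -> BandSimilarity:
    """Banded Hi-C similarity: ``s_ij = log(1 + count_ij)``.

    log1p keeps absent pairs consistent with the band assumption
    (``log(1 + 0) = 0``) while reducing the skew of raw counts.
    """
    if not (1 <= h <= C.p):
        raise ValueError(f"need 1 <= h <= p, got h={h}, p={C.p}")
    band = np.zeros((C.p, h))
    n_dropped = 0
    seen = set()
    for bi, bj, c in C.triplets:
        a, b = (int(bi), int(bj)) if bi <= bj else (int(bj), int(bi))
        if (a, b) in seen:
            raise ValueError(f"duplicate contact entry for bins ({a}, {b})")
        seen.add((a, b))
        d = b - a
        if d >= h:
            n_dropped += 1
            continue
        band[a, d] = np.log1p(float(c))
    if n_dropped:
        logger.info("dropped %d out-of-band contact pair(s)", n_dropped)
    return BandSimilarity(band)


def clusters_to_bed(labels, starts, chromosome: str,
                    chrom_end: int | None = None) -> pd.DataFrame:
    """Contiguous cluster labels -> BED records tiling the interval.

    ``starts`` gives the 0-based start coordinate of each object (bin
    start, or SNP position - 1).  Cluster ``k`` spans from the start of
    its first object to the start of the first object of cluster
    ``k + 1`` (the last cluster ends at ``chrom_end``, by default one
    past the last start), so the records tile the input interval with
    no gaps or overlaps.
    """
    labels = np.asarray(labels, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    if labels.shape != starts.shape:
        raise ValueError("labels and starts must have equal length")
    change = np.diff(labels)
    if np.any(change < 0) or np.any(change > 1) or labels[0] != 1:
        raise ValueError("labels must be contiguous blocks 1..K")
    if np.any(np.diff(starts) <= 0):
        raise ValueError("starts must be strictly increasing")
    firsts = np.concatenate(([0], np.nonzero(change == 1)[0] + 1))
    block_starts = starts[firsts]
    if chrom_end is None:
        chrom_end = int(starts[-1]) + 1
    block_ends = np.concatenate((block_starts[1:], [chrom_end]))
    return pd.DataFrame({
        "chrom": chromosome,
        "start": block_starts,
        "end": block_ends,
        "name": [f"cluster_{k}" for k in range(1, len(firsts) + 1)],
    })


class BandwidthNotStabilized(RuntimeError):
    """No bandwidth in the schedule reached the stability threshold."""

    def __init__(self, msg, trace):
        super().__init__(msg)
        self.trace = trace


def select_bandwidth(builder, h_schedule, stability: float = 1.0) -> int:
    """Data-driven bandwidth: smallest ``h`` with a stable dendrogram.

    ``builder(h)`` must return the :class:`BandSimilarity` at bandwidth
    ``h``.  The hierarchy is computed for each ``h`` in the increasing
    schedule and the first ``h`` whose first-difference index against
    the next schedule entry reaches ``stability`` is returned.  If the
    similarity has true bandwidth ``h0``, every ``h >= h0`` yields the
    identical hierarchy, so the selection terminates at the first
    schedule entry at or past ``h0``.
    """
    h_schedule = list(h_schedule)
    if len(h_schedule) < 2:
        raise ValueError("h_schedule must contain at least 2 bandwidths")
    if any(b <= a for a, b in zip(h_schedule, h_schedule[1:])):
        raise ValueError("h_schedule must be strictly increasing")
    dendros = [cluster(builder(h)) for h in h_schedule]
    trace = []
    for h, d1, d2 in zip(h_schedule, dendros, dendros[1:]):
        fdi = first_difference_index(d1, d2)
        trace.append((h, fdi))
        if fdi >= stability:
            return h
    raise BandwidthNotStabilized(
        f"no bandwidth in {h_schedule} reached stability {stability}",
        trace=pd.DataFrame(trace, columns=["h", "first_difference_index"]),
    )
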