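"""Choosing a number of clusters from a constrained dendrogram.

Two selectors are provided.  Both work from the merge heights read off
the dendrogram from the root: ``d_k``, the height of the k-th merge
from the top, is the decrease in within-cluster dispersion achieved by
the split that turns ``k`` clusters into ``k + 1``.

* **Broken stick** — compares each ``d_k`` to the expected size of the
  k-th largest piece of a stick of length ``T = sum d_k`` broken
  uniformly at random into ``p - 1`` pieces,
  ``b_k = T/(p-1) * sum_{i=k}^{p-1} 1/i``.  Starting from the root,
  stop at the first split whose observed decrease is no larger than its
  broken-stick expectation.  An ad hoc but widely used rule.
* **Slope heuristic** — statistically grounded for segmentation: with
  contrast ``C(K)`` = pseudo-inertia of the K-cluster partition and
  penalty shape ``pen(K) = log C(p-1, K-1)`` (the log binomial count of
  segmentations, evaluated with log-gamma so it stays finite at genomic
  ``p``), the penalty constant is estimated as the slope of ``C``
  against ``pen`` over the top half of the searched range (robust
  Theil-Sen fit), and the selected ``K`` minimizes
  ``C(K) + 2*kappa*pen(K)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import theilslopes

from .engine import Dendrogram

logger = logging.getLogger(__name__)


@dataclass
class ClusterSelection:
    """Chosen cluster count with labels and the per-K criterion trace."""

    n_clusters: int
    labels: np.ndarray
    method: str
    trace: pd.DataFrame = field(repr=False)


def _root_heights(D: Dendrogram) -> np.ndarray:
    """d_1..d_{p-1}: merge heights read from the root downwards."""
    d = D.height[::-1].copy()
    if np.any(d < 0):
        logger.warning(
            "dendrogram has negative heights (similarity not PSD); "
            "model selection proceeds on the raw values"
        )
    if not D.monotone:
        logger.warning("dendrogram heights are non-monotone (reversals)")
    return d


def select_broken_stick(D: Dendrogram) -> ClusterSelection:
    """Broken-stick cut: stop at the first unremarkable split."""
    p = D.p
    d = _root_heights(D)
    T = float(d.sum())
    n = p - 1
    # b_k = T/n * sum_{i=k}^{n} 1/i  (expected k-th largest piece)
    inv = 1.0 / np.arange(1, n + 1)
    b = (T / n) * np.cumsum(inv[::-1])[::-1]
    stops = np.nonzero(d <= b)[0]
    K = int(stops[0]) + 1 if stops.size else p
    trace = pd.DataFrame({
        "K": np.arange(1, n + 1),
        "decrease": d,
        "broken_stick": b,
    })
    return ClusterSelection(K, D.cut(K), "broken-stick", trace)


def default_k_max(p: int) -> int:
    """Search bound keeping pen(K) on its increasing branch."""
    return min(p - 1, 100, max(10, (p - 1) // 2))


def select_slope_heuristic(D: Dendrogram, k_max: int | None = None
                           ) -> ClusterSelection:
    """Slope-heuristic cut with penalty shape ``log C(p-1, K-1)``."""
    p = D.p
    if k_max is None:
        k_max = default_k_max(p)
    if not (1 <= k_max <= p):
        raise ValueError(f"need 1 <= k_max <= p, got {k_max}")
    k_max = min(k_max, p - 1)
    d = _root_heights(D)
    T = float(d.sum())
    K = np.arange(1, k_max + 1)
    # contrast: pseudo-inertia of the K-cluster partition
    C = T - np.concatenate(([0.0], np.cumsum(d)))[: k_max]
    pen = gammaln(p) - gammaln(K) - gammaln(p - K + 1)
    lo = max(int(np.ceil(k_max / 2)) - 1, 0)
    pw, cw = pen[lo:], C[lo:]
    if pw.size < 2 or np.ptp(pw) == 0:
        raise ValueError(
            "degenerate slope fit: penalty shape has no variation over "
            f"the fit window K in [{lo + 1}, {k_max}]"
        )
    slope = theilslopes(cw, pw).slope
    kappa = max(-float(slope), 0.0)
    crit = C + 2.0 * kappa * pen
    K_hat = int(np.argmin(crit)) + 1
    trace = pd.DataFrame({
        "K": K, "contrast": C, "pen": pen, "penalized": crit,
    })
    trace.attrs["kappa"] = kappa
    return ClusterSelection(K_hat, D.cut(K_hat), "slope-heuristic", trace)
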