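"""bandclust: adjacency-constrained Ward clustering of band similarities.

Segments linearly ordered genomic objects (SNPs, Hi-C bins) into
contiguous clusters by hierarchical agglomerative clustering in which
only adjacent clusters may merge.  Under the band assumption
(similarity 0 beyond a bandwidth ``h``) the full hierarchy is computed
in O(p(h + log p)) time and O(ph) memory via pencil cumulative sums
and a min-heap of candidate fusions.
"""

from .band import BandSimilarity
from .engine import (Dendrogram, MergeStep, cluster, first_difference_index,
                     naive_cluster)
from .estimators import AdjacencyConstrainedWard
from .genomics import (BandwidthNotStabilized, ContactMap, GenotypeMatrix,
                       clusters_to_bed, hic_band, ld_band, select_bandwidth)
from .heap import CandidateFusion, EmptyHeapError, FusionHeap
from .model_selection import (ClusterSelection, select_broken_stick,
                              select_slope_heuristic)
from .pencils import PencilSums
from .simulate import (PlantedStructure, gen_block_similarity,
                       gen_contact_map, gen_genotypes)

__version__ = "0.1.0"

__all__ = [
    "AdjacencyConstrainedWard",
    "BandSimilarity",
    "BandwidthNotStabilized",
    "CandidateFusion",
    "ClusterSelection",
    "ContactMap",
    "Dendrogram",
    "EmptyHeapError",
    "FusionHeap",
    "GenotypeMatrix",
    "MergeStep",
    "PencilSums",
    "PlantedStructure",
    "cluster",
    "clusters_to_bed",
    "cut",
    "first_difference_index",
    "gen_block_similarity",
    "gen_contact_map",
    "gen_genotypes",
    "hic_band",
    "ld_band",
    "naive_cluster",
    "select_bandwidth",
    "select_broken_stick",
    "select_slope_heuristic",
]


def cut(dendrogram: Dendrogram, K: int):
    """Labels (1..K, contiguous blocks) of the K-cluster partition."""
    return dendrogram.cut(K)
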