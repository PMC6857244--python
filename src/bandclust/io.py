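"""Readers and writers for the plain-text formats the tool exchanges.

Dense similarities travel as TSV/CSV (optional label header), sparse
similarities and contact maps as MatrixMarket coordinate files or
1-based 3-column TSV, genotypes as delimited dosage matrices or VCF,
clusterings as BED, and hierarchies as merge-table TSV or Newick.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .band import BandSimilarity
from .engine import Dendrogram
from .genomics import ContactMap, GenotypeMatrix

logger = logging.getLogger(__name__)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "," if ("," in line and "\t" not in line) else "\t"
    return "\t"


def read_dense_similarity(path) -> tuple[np.ndarray, list | None]:
    """Dense symmetric matrix from TSV/CSV; returns (matrix, labels).

    A header row (and matching first column) of non-numeric labels is
    detected and stripped.
    """
    def _numeric(x) -> bool:
        try:
            float(x)
        except (TypeError, ValueError):
            return False
        return True

    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    labels = None
    if not _numeric(df.iloc[0, df.shape[1] - 1]):  # header row of labels
        if not _numeric(df.iloc[1, 0]):  # matching label column
            labels = [str(x) for x in df.iloc[0, 1:]]
            df = df.iloc[1:, 1:]
        else:
            labels = [str(x) for x in df.iloc[0, :]]
            df = df.iloc[1:, :]
    M = df.to_numpy(dtype=float)
    return M, labels


def read_triplets(path) -> tuple[list[tuple[int, int, float]], int]:
    """Sparse entries from MatrixMarket or 1-based 3-column TSV.

    Returns (triplets, p) with 1-based indices; ``p`` is taken from the
    MatrixMarket header or from the largest index seen.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("%%MatrixMarket"):
        M = scipy.io.mmread(path)
        M = scipy.sparse.coo_matrix(M)
        p = max(M.shape)
        trips = [(int(i) + 1, int(j) + 1, float(v))
                 for i, j, v in zip(M.row, M.col, M.data)]
        # mmread expands symmetric storage; keep one triangle
        trips = [(i, j, v) for i, j, v in trips if i <= j]
        return trips, p
    df = pd.read_csv(path, sep=_sniff_sep(path), header=None, comment="#")
    if df.shape[1] != 3:
        raise ValueError("triplet file must have 3 columns: i, j, value")
    trips = [(int(i), int(j), float(v)) for i, j, v in df.itertuples(False)]
    p = max(max(i, j) for i, j, _ in trips) if trips else 0
    return trips, p


def read_band_similarity(path, fmt: str, h: int | None = None
                         ) -> BandSimilarity:
    """Load a similarity as a :class:`BandSimilarity`.

    ``fmt`` is ``"dense"`` or ``"coo"``; ``h`` defaults to ``p``.
    """
    if fmt == "dense":
        M, labels = read_dense_similarity(path)
        return BandSimilarity.from_dense(M, h=h, labels=labels)
    if fmt == "coo":
        trips, p = read_triplets(path)
        return BandSimilarity.from_triplets(trips, p=p, h=h or p)
    raise ValueError(f"unknown similarity format: {fmt!r}")


def read_contact_map(path, bin_size: int = 40_000,
                     chromosome: str = "chr1") -> ContactMap:
    """Contact map from 1-based (bin_i, bin_j, count) TSV or MatrixMarket."""
    trips, p = read_triplets(path)
    arr = np.array([(i - 1, j - 1, int(round(v))) for i, j, v in trips],
                   dtype=np.int64).reshape(-1, 3)
    return ContactMap(p=p, triplets=arr, bin_size=bin_size,
                      chromosome=chromosome)


def read_dosage_matrix(path) -> GenotypeMatrix:
    """Delimited dosage matrix, individuals in rows, SNPs in columns.

    An optional header row carries SNP identifiers; missing values may
    be empty, ``NA`` or ``.``.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#",
                     na_values=["NA", ".", ""])
    snp_ids = None
    cols_numeric = all(str(c).replace(".", "").lstrip("-").isdigit()
                       for c in df.columns)
    if not cols_numeric:
        snp_ids = [str(c) for c in df.columns]
    else:  # no header: re-read raw
        df = pd.read_csv(path, sep=sep, header=None, comment="#",
                         na_values=["NA", ".", ""])
    return GenotypeMatrix(dosages=df.to_numpy(dtype=float),
                          snp_ids=snp_ids)


def read_vcf(path) -> GenotypeMatrix:
    """Genotype dosages from a VCF (GT field; one chromosome).

    Multi-allelic sites are rejected with a message.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    dosage_rows, positions, ids = [], [], []
    chrom = None
    for v in vcf:
        if len(v.ALT) > 1:
            raise ValueError(
                f"multi-allelic site at {v.CHROM}:{v.POS} is not supported; "
                "split or filter it first"
            )
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            raise ValueError("VCF must contain a single chromosome")
        # with gts012=True: 0/1/2 = dosage, 3 = missing
        gt = np.asarray(v.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        dosage_rows.append(gt)
        positions.append(v.POS)
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
    if not dosage_rows:
        raise ValueError("VCF contains no variants")
    dosages = np.column_stack(dosage_rows)
    return GenotypeMatrix(dosages=dosages,
                          positions=np.asarray(positions, dtype=np.int64),
                          snp_ids=ids, chromosome=chrom or "chr1")


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path, header_comment: str | None = None):
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_merge_table(D: Dendrogram, path, header_comment=None) -> None:
    _write_tsv(D.to_table(), path, header_comment)


def read_merge_table(path) -> Dendrogram:
    df = pd.read_csv(path, sep="\t", comment="#")
    return Dendrogram.from_table(df)


def write_bed(bed: pd.DataFrame, path) -> None:
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_labels(labels, path, header_comment=None) -> None:
    df = pd.DataFrame({
        "index": np.arange(1, len(labels) + 1),
        "label": np.asarray(labels, dtype=np.int64),
    })
    _write_tsv(df, path, header_comment)
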