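"""UMI count QC, recovery normalization, and gene detection filtering.

Plate-based scRNA-seq (SORT-seq/CEL-Seq2) wells fail in two ways: empty or
dying cells yield few UMIs, doublets yield too many.  Cells are kept when
their UMI total lies within [5900, 111000] (bounds inclusive; "111.000" in
the protocol description uses a European thousands separator and means
111,000).  Per-cell mRNA recovery differences — including the 2-fold mRNA
content drop at cell division — are absorbed by size factors.  Genes enter
downstream analysis only when their mean raw count over G2/M cells reaches
2 in every plate, so that G1 downregulation cannot bias detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "CountsMatrix",
    "filter_cells_by_umi",
    "compute_size_factors",
    "filter_detected_genes",
    "UMI_LOWER",
    "UMI_UPPER",
    "MIN_DETECTION_MEAN",
]

UMI_LOWER = 5900
UMI_UPPER = 111_000
MIN_DETECTION_MEAN = 2.0


@dataclass
class CountsMatrix:
    """Genes x cells UMI counts with per-cell plate labels and size factors."""

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    counts: np.ndarray  # int, genes x cells
    plate_labels: np.ndarray
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids)
        self.cell_ids = np.asarray(self.cell_ids)
        self.counts = np.asarray(self.counts)
        self.plate_labels = np.asarray(self.plate_labels)
        if self.counts.shape != (self.gene_ids.size, self.cell_ids.size):
            raise ValueError("counts shape must be (n_genes, n_cells)")
        if self.plate_labels.size != self.cell_ids.size:
            raise ValueError("one plate label per cell required")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if np.any(self.size_factors <= 0):
                raise ValueError("size factors must be positive")

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    def cell_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def normalized(self) -> np.ndarray:
        """Counts divided by per-cell size factors (computed on demand)."""
        sf = self.size_factors
        if sf is None:
            sf = compute_size_factors(self)
        return self.counts / sf[None, :]

    def subset_cells(self, mask) -> "CountsMatrix":
        mask = np.asarray(mask)
        return CountsMatrix(
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[mask],
            counts=self.counts[:, mask],
            plate_labels=self.plate_labels[mask],
            size_factors=None if self.size_factors is None
            else self.size_factors[mask],
        )

    def subset_genes(self, mask) -> "CountsMatrix":
        mask = np.asarray(mask)
        return CountsMatrix(
            gene_ids=self.gene_ids[mask],
            cell_ids=self.cell_ids,
            counts=self.counts[mask, :],
            plate_labels=self.plate_labels,
            size_factors=self.size_factors,
        )

    # ---- I/O: MatrixMarket with TSV sidecars, or one wide TSV ----

    def to_mtx(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(out_dir / "counts.mtx"),
                     sparse.csr_matrix(self.counts))
        pd.DataFrame({"gene_id": self.gene_ids}).to_csv(
            out_dir / "genes.tsv", sep="\t", index=False)
        cells = pd.DataFrame({"cell_id": self.cell_ids,
                              "plate_id": self.plate_labels})
        if self.size_factors is not None:
            cells["size_factor"] = self.size_factors
        cells.to_csv(out_dir / "cells.tsv", sep="\t", index=False)

    @classmethod
    def from_mtx(cls, in_dir: str | Path) -> "CountsMatrix":
        in_dir = Path(in_dir)
        counts = np.asarray(spio.mmread(str(in_dir / "counts.mtx")).todense())
        genes = pd.read_csv(in_dir / "genes.tsv", sep="\t")
        cells = pd.read_csv(in_dir / "cells.tsv", sep="\t")
        return cls(
            gene_ids=genes["gene_id"].to_numpy(),
            cell_ids=cells["cell_id"].to_numpy(),
            counts=counts.astype(np.int64),
            plate_labels=cells["plate_id"].to_numpy(),
            size_factors=(cells["size_factor"].to_numpy()
                          if "size_factor" in cells else None),
        )

    def to_wide_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, index=self.gene_ids,
                          columns=self.cell_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


def filter_cells_by_umi(
    matrix: CountsMatrix,
    lower: int = UMI_LOWER,
    upper: int = UMI_UPPER,
) -> tuple[CountsMatrix, dict]:
    """Keep cells whose UMI total lies in [lower, upper] inclusive.

    Returns the filtered matrix and a report of removals by reason.
    """
    if lower > upper:
        raise ValueError("lower bound exceeds upper bound")
    totals = matrix.cell_totals()
    low = totals < lower
    high = totals > upper
    keep = ~(low | high)
    report = {
        "n_input": int(matrix.n_cells),
        "n_kept": int(keep.sum()),
        "n_removed_low_umi": int(low.sum()),
        "n_removed_high_umi": int(high.sum()),
        "lower": int(lower),
        "upper": int(upper),
    }
    return matrix.subset_cells(keep), report


def compute_size_factors(
    matrix: CountsMatrix,
    method: str = "geometric",
) -> np.ndarray:
    """Per-cell mRNA recovery size factors.

    ``geometric`` (default): cell total over the geometric mean of totals,
    so the mean log size factor is zero.  ``median_ratio``: per-cell median
    of count ratios to the per-gene geometric-mean reference (computed over
    genes expressed everywhere), the bulk RNA-seq median-of-ratios scheme.
    """
    totals = matrix.cell_totals().astype(float)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts cannot be normalized")
    if method == "geometric":
        return totals / np.exp(np.mean(np.log(totals)))
    if method == "median_ratio":
        counts = matrix.counts.astype(float)
        expressed = np.all(counts > 0, axis=1)
        if not expressed.any():
            raise ValueError("median-of-ratios needs genes detected in all cells")
        ref = np.exp(np.mean(np.log(counts[expressed]), axis=1))
        return np.median(counts[expressed] / ref[:, None], axis=0)
    raise ValueError(f"unknown size factor method: {method!r}")


def filter_detected_genes(
    matrix: CountsMatrix,
    g2m_cells,
    min_mean: float = MIN_DETECTION_MEAN,
) -> np.ndarray:
    """Boolean gene mask: mean raw count over G2/M cells >= min_mean in
    every plate.

    Averaging over G2/M cells (not all cells) keeps genes that are strongly
    downregulated in G1 from being filtered out by their own decline.
    """
    g2m_set = set(g2m_cells)
    is_g2m = np.array([c in g2m_set for c in matrix.cell_ids])
    if not is_g2m.any():
        raise ValueError("no G2/M cells present")
    keep = np.ones(matrix.n_genes, dtype=bool)
    for plate in np.unique(matrix.plate_labels):
        sel = is_g2m & (matrix.plate_labels == plate)
        if not sel.any():
            raise ValueError(f"plate {plate!r} has no G2/M cells")
        keep &= matrix.counts[:, sel].mean(axis=1) >= min_mean
    return keep
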