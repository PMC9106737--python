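"""Cell-by-gene matrix construction, filtering, normalization, clustering.

Spot-count matrices hold nonnegative integers whose total equals the number
of cell-assigned decoded spots; density matrices hold area-fractions in
[0, 1].  The analysis mirrors the standard single-cell workflow: filter
cells with too few counts, then genes expressed in too few cells; scale
each cell to a common total (the median by default) and log-transform;
cluster on a k-nearest-neighbour graph with Leiden community detection
(optionally after a PCA reduction).  Density matrices skip the count
normalization — the division by cell area is their size adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .cells import CellLabelMask

__all__ = [
    "CellQuantification",
    "build_matrix",
    "filter_matrix",
    "normalize_log",
    "area_normalize_density",
    "cluster_cells",
    "spot_density_correlation",
    "summarize_rcps_per_cell",
]


@dataclass
class CellQuantification:
    """A cells-by-genes matrix with per-cell geometry and provenance.

    ``mode`` is ``spot_counts`` (integer spot tallies), ``density``
    (area-fractions in [0, 1]) or ``density_counts`` (raw foreground-pixel
    tallies that still await exactly one division by cell area).  The mode
    flag is what guarantees the area division is applied exactly once.
    """

    matrix: np.ndarray
    cell_ids: np.ndarray
    genes: list[str]
    cell_meta: pd.DataFrame  # centroid_y, centroid_x, area_px (row-aligned)
    mode: str = "spot_counts"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        if self.matrix.shape != (len(self.cell_ids), len(self.genes)):
            raise ValueError("matrix shape must be (n_cells, n_genes)")
        if self.mode not in ("spot_counts", "density", "density_counts"):
            raise ValueError(f"unknown quantification mode {self.mode!r}")
        if self.mode == "spot_counts":
            if (self.matrix < 0).any() or not np.allclose(
                self.matrix, np.round(self.matrix)
            ):
                raise ValueError("spot-count matrices must hold nonnegative integers")
        if self.mode == "density" and (
            (self.matrix < 0).any() or (self.matrix > 1).any()
        ):
            raise ValueError("density matrices must lie in [0, 1]")

    @property
    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def build_matrix(
    assigned: pd.DataFrame, cells: CellLabelMask, gene_list: list[str]
) -> CellQuantification:
    """Tally cell-assigned decoded spots into a cells-by-genes count matrix.

    Unassigned spots (cell_id 0), ``unassigned`` gene labels and
    ``invalid_barcode`` calls are excluded; genes from ``gene_list`` with no
    spots are retained as zero columns.  A spot gene outside ``gene_list``
    is an error.
    """
    keep = assigned[
        (assigned["cell_id"] > 0)
        & (~assigned["gene"].isin(["", "unassigned", "invalid_barcode"]))
    ]
    unknown = sorted(set(keep["gene"]) - set(gene_list))
    if unknown:
        raise ValueError(f"spot genes not in gene_list: {unknown}")
    cell_ids = cells.cells["cell_id"].to_numpy(dtype=np.int64)
    gene_pos = {g: i for i, g in enumerate(gene_list)}
    cell_pos = {c: i for i, c in enumerate(cell_ids)}
    mat = np.zeros((len(cell_ids), len(gene_list)), dtype=np.int64)
    for cid, gene in zip(keep["cell_id"], keep["gene"]):
        mat[cell_pos[int(cid)], gene_pos[gene]] += 1
    meta = cells.cells.set_index("cell_id")[
        ["centroid_y", "centroid_x", "area_px"]
    ].reset_index(drop=True)
    return CellQuantification(
        matrix=mat,
        cell_ids=cell_ids,
        genes=list(gene_list),
        cell_meta=meta,
        mode="spot_counts",
        provenance={"n_spots_assigned": int(len(keep))},
    )


def filter_matrix(
    quant: CellQuantification, min_counts_per_cell: float, min_cells_per_gene: int
) -> CellQuantification:
    """Drop lowly covered cells, then lowly expressed genes (in that order).

    Cells with total < ``min_counts_per_cell`` go first; then genes
    expressed (nonzero) in fewer than ``min_cells_per_gene`` of the
    surviving cells.  Removals are recorded in the provenance.  Filtering
    everything away is an error suggesting gentler thresholds.
    """
    if min_counts_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("filter thresholds must be >= 0")
    cell_keep = quant.totals >= min_counts_per_cell
    mat = quant.matrix[cell_keep]
    gene_keep = (mat > 0).sum(axis=0) >= min_cells_per_gene
    if not cell_keep.any() or not gene_keep.any():
        raise ValueError(
            "filtering removed every cell or gene; relax min_counts_per_cell / "
            "min_cells_per_gene"
        )
    removed_cells = quant.cell_ids[~cell_keep].tolist()
    removed_genes = [g for g, k in zip(quant.genes, gene_keep) if not k]
    prov = dict(quant.provenance)
    prov["filtered_cells_low_counts"] = removed_cells
    prov["filtered_genes_low_cells"] = removed_genes
    return CellQuantification(
        matrix=mat[:, gene_keep],
        cell_ids=quant.cell_ids[cell_keep],
        genes=[g for g, k in zip(quant.genes, gene_keep) if k],
        cell_meta=quant.cell_meta.loc[cell_keep].reset_index(drop=True),
        mode=quant.mode,
        provenance=prov,
    )


def normalize_log(quant: CellQuantification, target_sum: float | None = None
                  ) -> np.ndarray:
    """Scale each cell's counts to a common total, then log(1 + x).

    ``target_sum`` defaults to the median of the per-cell totals.  Requires
    a filtered spot-count matrix; a zero-total cell reaching this stage is
    an error (the cell filter should have removed it).
    """
    if quant.mode != "spot_counts":
        raise ValueError("normalize_log applies to spot-count matrices")
    totals = quant.totals.astype(np.float64)
    if (totals == 0).any():
        raise ValueError("zero-total cell in normalize_log; filter cells first")
    if target_sum is None or target_sum == 0:
        target_sum = float(np.median(totals))
    scaled = quant.matrix * (target_sum / totals)[:, None]
    return np.log1p(scaled)


def area_normalize_density(quant: CellQuantification) -> np.ndarray:
    """Size-adjust a density matrix and log-transform it.

    If the matrix still holds raw foreground-pixel counts
    (``density_counts``) each row is divided by its cell's area; a matrix
    already in area-fractions is left as is — the mode flag guarantees the
    division happens exactly once.  Zero-area cells are an error.
    """
    if quant.mode == "density":
        frac = quant.matrix.astype(np.float64)
    elif quant.mode == "density_counts":
        areas = quant.cell_meta["area_px"].to_numpy(dtype=np.float64)
        if (areas <= 0).any():
            raise ValueError("zero-area cell in area_normalize_density")
        frac = quant.matrix / areas[:, None]
    else:
        raise ValueError("area_normalize_density applies to density matrices")
    return np.log1p(frac)


def cluster_cells(
    matrix: np.ndarray,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    pca_components: int | None = 20,
) -> np.ndarray:
    """Leiden community detection on a k-nearest-neighbour graph.

    The normalized matrix is optionally reduced by PCA (to
    ``min(pca_components, n_genes - 1, n_cells - 1)`` dimensions), a kNN
    graph built with Euclidean distances, symmetrized, and partitioned with
    Leiden (RB-configuration modularity) at the given resolution.
    Deterministic under a fixed seed; labels are 0..K-1.
    """
    x = np.asarray(matrix, dtype=np.float64)
    n_cells = x.shape[0]
    if n_cells < n_neighbors:
        raise ValueError(
            f"need at least n_neighbors={n_neighbors} cells, have {n_cells}"
        )
    if pca_components:
        n_comp = min(pca_components, x.shape[1] - 1, n_cells - 1)
        if n_comp >= 2:
            x = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    adj = kneighbors_graph(x, n_neighbors=n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    g = igraph.Graph(n=n_cells, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=np.int64)


def spot_density_correlation(
    counts: CellQuantification, densities: CellQuantification
) -> tuple[pd.DataFrame, dict]:
    """Per-gene Pearson correlation of spot counts against densities across
    the cells shared by the two quantifications.

    Cells missing from either side are excluded and counted in the returned
    info dict.  With fewer than 3 shared cells (or a constant vector) the
    correlation is reported as NaN.
    """
    shared = np.intersect1d(counts.cell_ids, densities.cell_ids)
    info = {
        "n_shared_cells": int(len(shared)),
        "n_only_counts": int(len(np.setdiff1d(counts.cell_ids, shared))),
        "n_only_density": int(len(np.setdiff1d(densities.cell_ids, shared))),
    }
    pos_a = {c: i for i, c in enumerate(counts.cell_ids)}
    pos_b = {c: i for i, c in enumerate(densities.cell_ids)}
    ia = [pos_a[c] for c in shared]
    ib = [pos_b[c] for c in shared]
    genes = [g for g in counts.genes if g in set(densities.genes)]
    rows = []
    for gene in genes:
        a = counts.matrix[ia, counts.genes.index(gene)].astype(np.float64)
        b = densities.matrix[ib, densities.genes.index(gene)].astype(np.float64)
        if len(shared) < 3 or a.std() == 0 or b.std() == 0:
            rows.append((gene, np.nan))
        else:
            rows.append((gene, float(pearsonr(a, b)[0])))
    return pd.DataFrame(rows, columns=["gene", "r"]), info


def summarize_rcps_per_cell(
    quant: CellQuantification,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene frequency table of per-cell RCP counts plus the mean
    count per cell (the dashed-line statistic of a counts-per-cell
    histogram panel).
    """
    if quant.mode != "spot_counts":
        raise ValueError("summarize_rcps_per_cell applies to spot-count matrices")
    rows = []
    means = {}
    for g, gene in enumerate(quant.genes):
        col = quant.matrix[:, g].astype(np.int64)
        means[gene] = float(col.mean()) if len(col) else np.nan
        vals, freq = np.unique(col, return_counts=True)
        for v, f in zip(vals, freq):
            rows.append((gene, int(v), int(f)))
    hist = pd.DataFrame(rows, columns=["gene", "count", "frequency"])
    return hist, pd.Series(means, name="mean_rcps_per_cell")
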