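"""Nuclei segmentation, cell-territory expansion and spot-to-cell assignment.

Nuclei come from the DAPI canvas by manual intensity threshold, hole
filling, a minimum-size gate and a watershed split of touching nuclei
(seeded at maxima of the distance transform).  Cell territories are the
nuclei expanded outward up to a distance cap; territories of neighbouring
cells meet at the equidistant ridge.  Decoded spots are assigned to the cell
whose territory contains their centroid pixel; background spots stay
unassigned but are retained.

The low-magnification mode skips individual spots entirely: per cell and
gene it scores the fraction of the cell's pixels whose filtered signal
clears a density threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import measure, morphology, segmentation
from skimage.feature import peak_local_max

__all__ = [
    "CellLabelMask",
    "segment_nuclei",
    "expand_to_cells",
    "assign_spots",
    "density_quantify",
]


@dataclass
class CellLabelMask:
    """Integer label image (0 = background, 1..N = cells) with per-cell
    area, centroid and the nucleus label each territory grew from."""

    labels: np.ndarray
    cells: pd.DataFrame  # cell_id, area_px, centroid_y, centroid_x, nucleus_label

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def cell_table(labels: np.ndarray, nucleus_labels: Mapping[int, int] | None = None
                ) -> pd.DataFrame:
    rows = []
    for prop in measure.regionprops(labels):
        cy, cx = prop.centroid
        nuc = nucleus_labels.get(prop.label, prop.label) if nucleus_labels else prop.label
        rows.append((int(prop.label), int(prop.area), cy, cx, int(nuc)))
    return pd.DataFrame(
        rows, columns=["cell_id", "area_px", "centroid_y", "centroid_x",
                       "nucleus_label"]
    )


def segment_nuclei(
    dapi_canvas: np.ndarray,
    dapi_threshold: float,
    min_nucleus_px: int,
    peak_min_distance_px: int = 6,
) -> np.ndarray:
    """Label nuclei on a DAPI canvas.

    Threshold -> fill holes -> drop objects below ``min_nucleus_px`` ->
    split touching nuclei by watershed on the negated distance transform,
    seeded at (lightly smoothed) distance-transform maxima at least
    ``peak_min_distance_px`` apart.  Returns an integer label image with
    labels 1..N; zero nuclei is a valid outcome.
    """
    if dapi_threshold <= 0:
        raise ValueError("dapi_threshold must be positive")
    mask = np.asarray(dapi_canvas) >= dapi_threshold
    mask = ndi.binary_fill_holes(mask)
    # drop objects below min_nucleus_px (max_size is inclusive)
    mask = morphology.remove_small_objects(mask, max_size=int(min_nucleus_px) - 1)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int64)
    dist = ndi.distance_transform_edt(mask)
    # smoothing keeps ragged mask edges from seeding spurious maxima
    smooth = ndi.gaussian_filter(dist, sigma=1.0)
    coords = peak_local_max(
        smooth, min_distance=int(peak_min_distance_px), labels=mask,
        exclude_border=False,
    )
    seeds = np.zeros(mask.shape, dtype=bool)
    seeds[tuple(coords.T)] = True
    markers, _ = ndi.label(seeds, structure=np.ones((3, 3)))
    if markers.max() == 0:  # tiny objects without a clean peak
        markers, _ = ndi.label(mask, structure=np.ones((3, 3)))
    labels = segmentation.watershed(-dist, markers, mask=mask)
    return segmentation.relabel_sequential(labels)[0].astype(np.int64)


def expand_to_cells(nucleus_mask: np.ndarray, max_expansion_px: float) -> CellLabelMask:
    """Grow each nucleus outward into an approximate cell territory.

    Expansion is capped at ``max_expansion_px`` beyond the nucleus boundary;
    competing nuclei meet at the equidistant ridge; pixels beyond every cap
    stay background.  Cell labels equal the nucleus labels they grew from.
    """
    nucleus_mask = np.asarray(nucleus_mask)
    expanded = segmentation.expand_labels(nucleus_mask, distance=max_expansion_px)
    return CellLabelMask(
        labels=expanded.astype(np.int64),
        cells=cell_table(expanded.astype(np.int64)),
    )


def assign_spots(decoded: pd.DataFrame, cells: CellLabelMask) -> pd.DataFrame:
    """Assign each spot to the cell whose territory contains its centroid.

    ``cell_id`` is the label at the rounded centroid pixel; label 0 means
    background — the spot is kept but excluded from the expression matrix.
    A spot outside the canvas is an error naming the spot.
    """
    labels = cells.labels
    h, w = labels.shape
    out = decoded.copy()
    ids = np.empty(len(out), dtype=np.int64)
    for i, (y, x) in enumerate(zip(out["y"], out["x"])):
        yi, xi = int(round(y)), int(round(x))
        if not (0 <= yi < h and 0 <= xi < w):
            ident = out.iloc[i].get("spot_id", i)
            raise ValueError(
                f"spot {ident} at (y={y:.1f}, x={x:.1f}) lies outside the canvas"
            )
        ids[i] = labels[yi, xi]
    out["cell_id"] = ids
    return out


def density_quantify(
    canvases_by_gene: Mapping[str, np.ndarray],
    cells: CellLabelMask,
    density_threshold: float,
):
    """Low-magnification quantification: per cell and gene, the fraction of
    the cell's area covered by signal above the density threshold.

    ``canvases_by_gene`` maps each gene to its top-hat-filtered canvas (one
    gene per round-channel in the low-magnification sequential mode).
    Returns a density-mode :class:`~rcpdecode.expression.CellQuantification`
    with entries in [0, 1].
    """
    from .expression import CellQuantification  # local: avoid import cycle

    genes = list(canvases_by_gene)
    cell_ids = cells.cells["cell_id"].to_numpy(dtype=np.int64)
    areas = cells.cells["area_px"].to_numpy(dtype=np.float64)
    mat = np.zeros((len(cell_ids), len(genes)), dtype=np.float64)
    labels = cells.labels
    n_labels = int(labels.max()) + 1
    for g, gene in enumerate(genes):
        fg = np.asarray(canvases_by_gene[gene]) >= density_threshold
        counts = np.bincount(labels[fg].ravel(), minlength=n_labels)
        mat[:, g] = counts[cell_ids] / areas
    meta = cells.cells.set_index("cell_id")[
        ["centroid_y", "centroid_x", "area_px"]
    ].reset_index(drop=True)
    return CellQuantification(
        matrix=mat, cell_ids=cell_ids, genes=genes, cell_meta=meta, mode="density"
    )
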