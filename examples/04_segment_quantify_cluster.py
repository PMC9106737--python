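"""From images to a clustered cell-by-gene matrix.

Segments nuclei from DAPI, expands them into cell territories, assigns
decoded spots to cells, builds the count matrix, and runs the standard
filter -> normalize -> log -> Leiden analysis on a planted two-population
mixture to show cluster recovery.
"""

import numpy as np

import rcpdecode as rd
from rcpdecode import fixtures, pipeline
from rcpdecode.expression import cluster_cells, normalize_log
from rcpdecode.simulate import planted_expression_matrix

# --- image-based quantification
sim, codebook, cfg = fixtures.segmentation_fixture(seed=2)
tileset, truth = rd.simulate.simulate_experiment(sim, codebook)
canvases, _ = pipeline.project_and_stitch(tileset, cfg)
filtered = pipeline.filter_canvases(canvases, sim.layout, cfg)
detected = pipeline.detect_all(filtered, sim.layout, cfg)
called = pipeline.decode_sequential(detected, codebook)
nuclei, mask = pipeline.segment(canvases, sim.layout, cfg)
assigned, quant = pipeline.quantify_spots(called, mask, codebook.genes)
print(f"segmented {mask.n_cells} cells (true: {len(truth.cells)}); "
      f"matrix total {int(quant.matrix.sum())} spots, "
      f"{int((assigned['cell_id'] == 0).sum())} background spots excluded")

# --- clustering a planted mixture
import pandas as pd

from rcpdecode.expression import CellQuantification

counts, pops, genes = planted_expression_matrix(2, 100, seed=21)
meta = pd.DataFrame({"centroid_y": 0.0, "centroid_x": 0.0, "area_px": 1},
                    index=range(len(counts)))
mix = CellQuantification(matrix=counts, cell_ids=np.arange(1, len(counts) + 1),
                         genes=genes, cell_meta=meta)
labels = cluster_cells(normalize_log(mix), n_neighbors=15, resolution=0.3,
                       seed=7)
agree = max(
    (labels == pops).mean(), (labels == 1 - pops).mean()
)  # best of the two label orders
print(f"planted 2 populations of 100 cells -> {labels.max() + 1} clusters, "
      f"label agreement {agree:.2f}")
# Agreement near 1.0: marker-block expression separates the populations
# cleanly on the kNN graph.
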