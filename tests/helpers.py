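"""Small builders shared across test modules."""

import numpy as np
import pandas as pd

from rcpdecode.decode import BarcodeCandidate
from rcpdecode.expression import CellQuantification


def candidate(qs, ds, channels=None, spot_ids=None, y=0.0, x=0.0):
    n = len(qs)
    return BarcodeCandidate(
        spot_ids=tuple(spot_ids or range(n)),
        channels=tuple(channels or [1] * n),
        qualities=tuple(qs),
        distances=tuple(ds),
        y=y,
        x=x,
    )


def make_quant(matrix, mode="spot_counts", ids=None, areas=None):
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    ids = np.arange(1, n + 1) if ids is None else np.asarray(ids)
    meta = pd.DataFrame(
        {
            "centroid_y": np.zeros(n),
            "centroid_x": np.zeros(n),
            "area_px": np.full(n, 100) if areas is None else np.asarray(areas),
        }
    )
    genes = [f"g{i}" for i in range(matrix.shape[1])]
    return CellQuantification(matrix=matrix, cell_ids=ids, genes=genes,
                              cell_meta=meta, mode=mode)
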