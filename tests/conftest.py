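"""Shared fixtures: standard pipeline runs on the canonical simulations.

The expensive simulated runs are session-scoped; tests treat them as
read-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import rcpdecode as rd
from rcpdecode import fixtures, pipeline


@dataclass
class PipelineRun:
    """Everything the standard spot pipeline produces on one experiment."""

    sim: rd.simulate.SimulationConfig
    codebook: rd.Codebook
    cfg: rd.RunConfig
    tileset: rd.TileSet
    truth: rd.simulate.GroundTruth
    canvases: dict
    stitch_info: dict
    filtered: dict
    detected: pd.DataFrame
    decoded: pd.DataFrame
    decode_diag: dict
    nuclei: np.ndarray
    mask: object
    assigned: pd.DataFrame
    quant: object

    def seg_label_of_truth_cell(self) -> dict[int, int]:
        """Map ground-truth cell ids to segmentation labels (via the label
        under each true nucleus centre)."""
        return {
            int(c.cell_id): int(self.mask.labels[int(round(c.y)), int(round(c.x))])
            for c in self.truth.cells.itertuples()
        }


def run_standard_pipeline(sim, codebook, cfg) -> PipelineRun:
    tileset, truth = rd.simulate.simulate_experiment(sim, codebook)
    canvases, info = pipeline.project_and_stitch(tileset, cfg)
    filtered = pipeline.filter_canvases(canvases, tileset.layout, cfg)
    detected = pipeline.detect_all(filtered, tileset.layout, cfg)
    diag = {}
    if codebook.mode == "sequential":
        decoded = pipeline.decode_sequential(detected, codebook)
    else:
        decoded, diag = pipeline.decode_combinatorial(detected, codebook, cfg)
    nuclei, mask = pipeline.segment(canvases, tileset.layout, cfg)
    assigned, quant = pipeline.quantify_spots(decoded, mask, codebook.genes)
    return PipelineRun(
        sim=sim, codebook=codebook, cfg=cfg, tileset=tileset, truth=truth,
        canvases=canvases, stitch_info=info, filtered=filtered,
        detected=detected, decoded=decoded, decode_diag=diag,
        nuclei=nuclei, mask=mask, assigned=assigned, quant=quant,
    )


@pytest.fixture(scope="session")
def seg_run() -> PipelineRun:
    """Default-scale sequential run (segmentation/assignment fixture)."""
    return run_standard_pipeline(*fixtures.segmentation_fixture(seed=2))


@pytest.fixture(scope="session")
def comb_run() -> PipelineRun:
    """Two-cycle, eight-gene combinatorial run."""
    return run_standard_pipeline(*fixtures.combinatorial_fixture(seed=3))


@pytest.fixture(scope="session")
def detection_run() -> PipelineRun:
    """Low-SNR single-tile detection benchmark."""
    return run_standard_pipeline(*fixtures.detection_fixture(seed=0))
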