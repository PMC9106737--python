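"""Canonical simulated study fixtures.

Each function bundles one benchmark condition — the simulation parameters
and the matching analysis settings — so that tests, examples and the
reproduction script all run the identical experiment.  Geometry and rates
are fixed here once; only the random seed varies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import pipeline
from .simio import AcquisitionLayout, Codebook, RunConfig
from .simulate import SimulationConfig, default_codebook, paired_condition_fixture

__all__ = [
    "detection_fixture",
    "stitch_fixture",
    "combinatorial_fixture",
    "segmentation_fixture",
    "snr_fixture",
    "slope_fixture_config",
    "run_slope_recovery",
    "density_fixture",
]


def detection_fixture(seed: int = 0) -> tuple[SimulationConfig, Codebook, RunConfig]:
    """Single 256x256 tile at spot amplitude = 5x noise sd, ~40 spots.

    A low-SNR detection benchmark: spots are kept >= 8 px apart so recall
    and precision measure the detector, not optical crowding.  The analysis
    settings enable the matched pre-smoothing that regime requires.
    """
    layout = AcquisitionLayout(tile_height_px=256, tile_width_px=256, z_steps=1)
    sim = SimulationConfig(
        layout=layout,
        n_cells=10,
        nucleus_radius_px=(6.0, 0.8),
        cell_radius_px=14.0,
        spots_per_cell_per_gene=1.0,
        psf_sigma_px=1.6,
        spot_amplitude=5000.0,
        gaussian_noise_sd=1000.0,
        background_level=3000.0,
        min_spot_separation_px=8.0,
        seed=seed,
    )
    cfg = RunConfig(
        detect_threshold=1100.0, detect_smooth_sigma_px=1.2, size_min_px=4
    )
    return sim, default_codebook(layout, 4), cfg


def stitch_fixture(seed: int = 0, jitter: int = 3
                   ) -> tuple[SimulationConfig, Codebook, RunConfig]:
    """3x3 grid of 128 px tiles, 10% overlap, integer stage jitter.

    Nuclei are dense enough that every overlap strip carries texture for the
    correlation search.
    """
    layout = AcquisitionLayout(
        grid_rows=3, grid_cols=3, tile_height_px=128, tile_width_px=128, z_steps=1
    )
    sim = SimulationConfig(
        layout=layout,
        n_cells=90,
        nucleus_radius_px=(5.0, 0.8),
        cell_radius_px=7.0,
        spots_per_cell_per_gene=0.5,
        tile_offset_jitter_px=jitter,
        seed=seed,
    )
    return sim, default_codebook(layout, 4), RunConfig()


def combinatorial_fixture(seed: int = 0
                          ) -> tuple[SimulationConfig, Codebook, RunConfig]:
    """2-cycle, 8-gene combinatorial run at low spot density.

    Perfect cross-cycle alignment (single tile, no jitter) and 5% channel
    crosstalk, so the q and Q scores operate on realistic purity values.
    """
    layout = AcquisitionLayout(
        tile_height_px=400, tile_width_px=400, n_rounds=2, z_steps=1
    )
    sim = SimulationConfig(
        layout=layout,
        n_cells=12,
        spots_per_cell_per_gene=1.0,
        crosstalk_fraction=0.05,
        min_spot_separation_px=6.0,
        seed=seed,
    )
    return sim, default_codebook(layout, 8, mode="combinatorial"), RunConfig()


def segmentation_fixture(seed: int = 0
                         ) -> tuple[SimulationConfig, Codebook, RunConfig]:
    """Default-scale single-tile experiment for segmentation/assignment:
    30 well-separated cells, 512x512 canvas, 4 sequential genes."""
    layout = AcquisitionLayout(tile_height_px=512, tile_width_px=512, z_steps=3)
    sim = SimulationConfig(layout=layout, n_cells=30, seed=seed)
    return sim, default_codebook(layout, 4), RunConfig()


def snr_fixture(seed: int = 0) -> tuple[SimulationConfig, Codebook, RunConfig]:
    """Sparse spots with analytic SNR = amplitude / noise sd = 10."""
    layout = AcquisitionLayout(tile_height_px=256, tile_width_px=256, z_steps=1)
    sim = SimulationConfig(
        layout=layout,
        n_cells=8,
        spots_per_cell_per_gene=0.5,
        spot_amplitude=10000.0,
        gaussian_noise_sd=1000.0,
        background_level=3000.0,
        min_spot_separation_px=12.0,
        seed=seed,
    )
    return sim, default_codebook(layout, 4), RunConfig(detect_threshold=4000.0)


# ---------------------------------------------------------------------------
# detection-efficiency slope recovery


def slope_fixture_config(seed: int) -> tuple[SimulationConfig, Codebook, RunConfig]:
    """One ROI of the paired chemistry-comparison fixture.

    A 2000 px square field with 800 cells and four genes at staggered
    abundances (expected low-efficiency totals ~200-1200 per gene per ROI).
    Rates sit in the sparse regime — a count-based efficiency comparison
    assumes resolvable spots, so the fixture avoids optical crowding.
    """
    layout = AcquisitionLayout(tile_height_px=2000, tile_width_px=2000, z_steps=1)
    sim = SimulationConfig(
        layout=layout,
        n_cells=800,
        nucleus_radius_px=(6.0, 1.0),
        cell_radius_px=35.0,
        spots_per_cell_per_gene=0.5,
        gene_rate_factors=(0.5, 1.0, 2.0, 3.0),
        psf_sigma_px=1.0,
        seed=seed,
    )
    return sim, default_codebook(layout, 4), RunConfig(detect_threshold=8000.0)


def run_slope_recovery(ratio: float, seed: int = 0, n_rois: int = 3
                       ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Detection-efficiency slope recovery across paired ROIs.

    For each ROI a paired experiment is simulated with ground-truth rate
    ratio ``ratio``; both conditions run the full detection pipeline
    (project, stitch, filter, detect, sequential gene assignment) and spot
    totals are summed per (ROI, gene).  Returns (slope, Pearson r,
    condition-A totals, condition-B totals).
    """
    from . import decode as decode_mod

    tot_a: list[list[int]] = []
    tot_b: list[list[int]] = []
    for roi in range(n_rois):
        sim, codebook, cfg = slope_fixture_config(seed * 1000 + roi)
        (ts_a, _), (ts_b, _) = paired_condition_fixture(sim, codebook, ratio)
        for ts, acc in ((ts_a, tot_a), (ts_b, tot_b)):
            canvases, _ = pipeline.project_and_stitch(ts, cfg)
            filtered = pipeline.filter_canvases(canvases, ts.layout, cfg)
            detected = pipeline.detect_all(filtered, ts.layout, cfg)
            called = pipeline.decode_sequential(detected, codebook)
            counts = called[called["gene"] != "unassigned"].groupby("gene").size()
            acc.append([int(counts.get(g, 0)) for g in codebook.genes])
    a, b = np.asarray(tot_a), np.asarray(tot_b)
    slope, r = decode_mod.efficiency_slope(a, b)
    return slope, r, a, b


def density_fixture(seed: int = 0) -> tuple[SimulationConfig, Codebook, RunConfig]:
    """High-magnification run used for the spot-vs-density comparison.

    Cells carry a log-normal expression scale (cell-type heterogeneity) so
    the per-gene correlation between spot counts and downsampled density
    maps measures real per-cell differences rather than Poisson noise, and
    rates stay in the resolvable-spot regime at 20X.
    """
    layout = AcquisitionLayout(tile_height_px=800, tile_width_px=800, z_steps=1)
    sim = SimulationConfig(
        layout=layout,
        n_cells=45,
        nucleus_radius_px=(7.0, 1.0),
        cell_radius_px=25.0,
        spots_per_cell_per_gene=8.0,
        cell_expression_sigma=0.6,
        psf_sigma_px=1.2,
        seed=seed,
    )
    return sim, default_codebook(layout, 4), RunConfig(detect_threshold=8000.0)


def run_density_comparison(seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Spot counting at 20X versus density quantification at emulated 10X.

    Runs the full spot pipeline on the high-magnification fixture, then
    emulates 10X acquisition by 2x block-mean downsampling of the same
    stitched canvases, quantifies per-cell signal density (threshold 2500 on
    the top-hat of the downsampled canvases, structuring radius 2) against
    the downsampled segmentation, and correlates the two per gene.
    Returns the per-gene Pearson table and the shared-cell info dict.
    """
    from . import cells as cells_mod, register, simulate, spots as spots_mod
    from .cells import CellLabelMask, cell_table
    from .expression import spot_density_correlation

    sim, codebook, cfg = density_fixture(seed)
    tileset, _ = simulate.simulate_experiment(sim, codebook)
    canvases, _ = pipeline.project_and_stitch(tileset, cfg)
    filtered = pipeline.filter_canvases(canvases, tileset.layout, cfg)
    detected = pipeline.detect_all(filtered, tileset.layout, cfg)
    called = pipeline.decode_sequential(detected, codebook)
    _, mask = pipeline.segment(canvases, tileset.layout, cfg)
    _, counts = pipeline.quantify_spots(called, mask, codebook.genes)

    low_labels = mask.labels[::2, ::2]
    low_mask = CellLabelMask(labels=low_labels, cells=cell_table(low_labels))
    by_gene = {
        gene: spots_mod.tophat_filter(
            register.downscale(canvases[rc], 2, "mean"), 2
        )
        for gene, rc in codebook.entries.items()
    }
    densities = cells_mod.density_quantify(by_gene, low_mask, 2500.0)
    return spot_density_correlation(counts, densities)
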