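"""End-to-end pipeline stages: the glue the CLI, examples and tests share.

Each stage is a plain function from in-memory objects to in-memory objects;
the CLI adds file I/O around them.  Stage order follows the acquisition's
natural flow: project + stitch -> background filter -> detect + quality ->
decode -> segment -> quantify -> analyse.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import cells as cells_mod
from . import decode as decode_mod
from . import register, spots as spots_mod
from .expression import CellQuantification, build_matrix
from .simio import AcquisitionLayout, Codebook, RunConfig, TileSet

__all__ = [
    "project_and_stitch",
    "filter_canvases",
    "detect_all",
    "decode_sequential",
    "decode_combinatorial",
    "segment",
    "quantify_spots",
    "match_points",
]


def project_and_stitch(
    tileset: TileSet, config: RunConfig
) -> tuple[dict[tuple[int, int], np.ndarray], dict]:
    """Collapse z, stitch each round on its nuclear channel, apply the
    per-round stitch to every channel, then align rounds to round 0.

    Returns the aligned canvases keyed by (round, channel) and a
    diagnostics record (per-round tile offsets, round shifts, fallback
    counts).
    """
    layout = tileset.layout
    per_round: list[dict[int, np.ndarray]] = []
    info: dict = {"rounds": [], "n_fallbacks": 0}
    for r in range(layout.n_rounds):
        projected = {
            c: {
                t: register.max_project(tileset.stack(t, r, c))
                for t in range(layout.n_tiles)
            }
            for c in range(layout.n_channels)
        }
        _, slayout = register.stitch(
            projected[layout.nuclear_channel],
            layout,
            search_margin_px=config.stitch_margin_px,
            min_confidence=config.min_stitch_confidence,
        )
        canvases = {
            c: register.apply_stitch(projected[c], slayout)
            for c in range(layout.n_channels)
        }
        per_round.append(canvases)
        info["rounds"].append(
            {"offsets": dict(slayout.offsets), "n_fallbacks": slayout.n_fallbacks}
        )
        info["n_fallbacks"] += slayout.n_fallbacks
    aligned, shifts = register.align_rounds(
        per_round, layout.nuclear_channel, search_margin_px=config.align_margin_px
    )
    info["round_shifts"] = shifts
    return (
        {(r, c): img for r, d in enumerate(aligned) for c, img in d.items()},
        info,
    )


def filter_canvases(
    canvases: Mapping[tuple[int, int], np.ndarray],
    layout: AcquisitionLayout,
    config: RunConfig,
) -> dict[tuple[int, int], np.ndarray]:
    """Top-hat filter every signal-channel canvas (nuclear left raw).

    With ``detect_smooth_sigma_px`` > 0 a Gaussian matched filter is applied
    to the raw canvas first — the standard lever for calling spots whose
    peak amplitude is only a few noise standard deviations.
    """
    import scipy.ndimage as ndi

    out = {}
    for (r, c), img in canvases.items():
        if c not in layout.signal_channels:
            continue
        if config.detect_smooth_sigma_px > 0:
            img = ndi.gaussian_filter(
                np.asarray(img, dtype=np.float64), config.detect_smooth_sigma_px
            )
        out[(r, c)] = spots_mod.tophat_filter(img, config.tophat_radius_px)
    return out


def detect_all(
    filtered: Mapping[tuple[int, int], np.ndarray],
    layout: AcquisitionLayout,
    config: RunConfig,
) -> pd.DataFrame:
    """Detect spots on every (round, signal channel) canvas and attach the
    channel-purity quality q.  Spot ids are unique within each round."""
    tables = []
    for r in range(layout.n_rounds):
        per_round = []
        for pos, c in enumerate(layout.signal_channels):
            df = spots_mod.detect_spots(
                filtered[(r, c)],
                config.threshold_for(pos),
                config.size_min_px,
                config.size_max_px,
                round_index=r,
                channel=c,
            )
            per_round.append(df)
        round_df = pd.concat(per_round, ignore_index=True)
        round_df["spot_id"] = np.arange(len(round_df), dtype=np.int64)
        tables.append(round_df)
    all_spots = pd.concat(tables, ignore_index=True)
    return spots_mod.measure_quality(
        all_spots, filtered, layout, floor=config.quality_floor
    )


def decode_sequential(spots: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    return decode_mod.assign_sequential(spots, codebook)


def decode_combinatorial(
    spots: pd.DataFrame, codebook: Codebook, config: RunConfig
) -> tuple[pd.DataFrame, dict]:
    """Link spots across the first ``n_cycles`` rounds, score with Q and
    call genes through the Q > 0 filter."""
    n_cycles = codebook.n_cycles
    per_cycle = [
        spots[spots["round"] == r].reset_index(drop=True) for r in range(n_cycles)
    ]
    candidates = decode_mod.link_cycles(per_cycle, config.link_radius_px)
    for cand in candidates:
        cand.Q = decode_mod.score_barcode(cand, config.k)
    return decode_mod.filter_and_call(candidates, codebook)


def segment(
    canvases: Mapping[tuple[int, int], np.ndarray],
    layout: AcquisitionLayout,
    config: RunConfig,
) -> tuple[np.ndarray, cells_mod.CellLabelMask]:
    """Segment nuclei on the round-0 nuclear canvas and expand to cells."""
    dapi = canvases[(0, layout.nuclear_channel)]
    nuclei = cells_mod.segment_nuclei(
        dapi,
        config.dapi_threshold,
        config.min_nucleus_px,
        peak_min_distance_px=config.nucleus_peak_min_distance_px,
    )
    return nuclei, cells_mod.expand_to_cells(nuclei, config.max_expansion_px)


def quantify_spots(
    decoded: pd.DataFrame,
    mask: cells_mod.CellLabelMask,
    genes: Sequence[str],
) -> tuple[pd.DataFrame, CellQuantification]:
    """Assign decoded spots to cells and tally the count matrix."""
    assigned = cells_mod.assign_spots(decoded, mask)
    return assigned, build_matrix(assigned, mask, list(genes))


def match_points(
    detected: np.ndarray, truth: np.ndarray, max_dist: float
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Greedy one-to-one matching of detected points to ground-truth points.

    Pairs are accepted nearest-first up to ``max_dist``.  Returns the list
    of (detected index, truth index) pairs and their distances — the basis
    for recall/precision/centroid-error evaluation against a simulation.
    """
    detected = np.asarray(detected, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if len(detected) == 0 or len(truth) == 0:
        return [], np.empty(0)
    tree = cKDTree(truth)
    # all candidate pairs within range, globally sorted by distance
    pairs = []
    dists, idx = tree.query(detected, k=min(3, len(truth)),
                            distance_upper_bound=max_dist)
    dists = np.atleast_2d(dists)
    idx = np.atleast_2d(idx)
    for i in range(len(detected)):
        for d, j in zip(dists[i], idx[i]):
            if np.isfinite(d):
                pairs.append((d, i, int(j)))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches = []
    match_d = []
    for d, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matches.append((i, j))
        match_d.append(d)
    return matches, np.asarray(match_d)
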