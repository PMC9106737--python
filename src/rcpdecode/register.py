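"""Z-projection, tile stitching and cross-round alignment.

Stitching follows the contract of translation-only grid stitchers (MIST and
kin): every grid-adjacent tile pair contributes a pairwise integer offset
estimated by normalized cross-correlation of the nominal overlap strips
within a small search window; global positions are obtained by anchoring
tile 0 and propagating offsets along a maximum-confidence spanning tree.
Overlap pixels are blended by per-pixel maximum so seam-straddling RCPs keep
their peak intensity.  All offsets are integer pixels; downstream barcode
linking tolerates the residual sub-pixel error through its distance penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .simio import AcquisitionLayout

__all__ = [
    "StitchLayout",
    "max_project",
    "estimate_pairwise_offset",
    "stitch",
    "apply_stitch",
    "estimate_shift",
    "shift_image",
    "align_rounds",
    "downscale",
]


@dataclass
class StitchLayout:
    """Final integer tile offsets in canvas coordinates plus diagnostics."""

    offsets: dict[int, tuple[int, int]]
    canvas_shape: tuple[int, int]
    tile_shape: tuple[int, int]
    edge_confidences: dict[tuple[int, int], float] = field(default_factory=dict)
    n_fallbacks: int = 0  # low-confidence pairs that kept their nominal offset
    round_shifts: dict[int, tuple[int, int]] = field(default_factory=dict)


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum intensity projection of a z-stack along its first axis."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("max_project expects a non-empty (z, y, x) stack")
    return stack.max(axis=0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _overlap_slices(shape_a, shape_b, offset):
    """Index ranges of the overlap of image B placed at ``offset`` in A's
    frame; returns None when the overlap is empty."""
    dy, dx = offset
    y0, y1 = max(0, dy), min(shape_a[0], dy + shape_b[0])
    x0, x1 = max(0, dx), min(shape_a[1], dx + shape_b[1])
    if y1 <= y0 or x1 <= x0:
        return None
    a = (slice(y0, y1), slice(x0, x1))
    b = (slice(y0 - dy, y1 - dy), slice(x0 - dx, x1 - dx))
    return a, b


def estimate_pairwise_offset(
    img_a: np.ndarray,
    img_b: np.ndarray,
    nominal_offset: tuple[int, int],
    search_margin_px: int = 5,
) -> tuple[int, int, float]:
    """Residual translation of tile B against tile A around a nominal offset.

    Scans integer residuals within ``+-search_margin_px`` of the nominal
    offset and returns the one maximizing the Pearson correlation of the
    overlap strips, with that peak correlation as confidence in [-1, 1].
    Candidates are visited nearest-nominal first, so ties keep the smallest
    residual.  Degenerate (constant) strips return the nominal offset with
    confidence 0.
    """
    img_a, img_b = np.asarray(img_a), np.asarray(img_b)
    nominal = (int(nominal_offset[0]), int(nominal_offset[1]))
    at_nominal = _overlap_slices(img_a.shape, img_b.shape, nominal)
    if at_nominal is None:
        raise ValueError("nominal offset implies no overlap between the tiles")
    sa, sb = at_nominal
    if min(sa[0].stop - sa[0].start, sa[1].stop - sa[1].start) < 8:
        raise ValueError("nominal overlap strip is thinner than 8 px")
    if img_a[sa].std() == 0 or img_b[sb].std() == 0:
        return 0, 0, 0.0

    m = int(search_margin_px)
    candidates = sorted(
        ((ry, rx) for ry in range(-m, m + 1) for rx in range(-m, m + 1)),
        key=lambda r: (abs(r[0]) + abs(r[1]), r[0], r[1]),
    )
    best = (0, 0, -np.inf)
    for ry, rx in candidates:
        sl = _overlap_slices(
            img_a.shape, img_b.shape, (nominal[0] + ry, nominal[1] + rx)
        )
        if sl is None:
            continue
        a, b = sl
        if (a[0].stop - a[0].start) * (a[1].stop - a[1].start) < 64:
            continue
        r = _pearson(img_a[a], img_b[b])
        if r > best[2]:
            best = (ry, rx, r)
    if not np.isfinite(best[2]):
        return 0, 0, 0.0
    return best


def stitch(
    tiles: Mapping[int, np.ndarray],
    layout: AcquisitionLayout,
    search_margin_px: int = 5,
    min_confidence: float = 0.3,
) -> tuple[np.ndarray, StitchLayout]:
    """Assemble one round-channel's projected tiles into a stitched canvas.

    Pairwise offsets are estimated for every grid-adjacent pair; pairs whose
    correlation confidence falls below ``min_confidence`` fall back to their
    nominal offset (counted in the returned layout's ``n_fallbacks``).
    Global positions anchor tile 0 and propagate along the
    maximum-confidence spanning tree; overlaps blend by per-pixel maximum.
    """
    if set(tiles) != set(range(layout.n_tiles)):
        raise ValueError("tiles must cover exactly the layout's tile indices")
    tile_shape = np.asarray(tiles[0]).shape
    for t, img in tiles.items():
        if np.asarray(img).shape != tile_shape:
            raise ValueError(f"tile {t} shape differs from tile 0")

    g = nx.Graph()
    g.add_nodes_from(range(layout.n_tiles))
    confidences: dict[tuple[int, int], float] = {}
    n_fallbacks = 0
    for t in range(layout.n_tiles):
        row, col = layout.tile_rowcol(t)
        for dr, dc in ((0, 1), (1, 0)):
            r2, c2 = row + dr, col + dc
            if r2 >= layout.grid_rows or c2 >= layout.grid_cols:
                continue
            u = layout.tile_index(r2, c2)
            nominal = (dr * layout.step_y, dc * layout.step_x)
            ry, rx, conf = estimate_pairwise_offset(
                tiles[t], tiles[u], nominal, search_margin_px
            )
            if conf < min_confidence:
                ry = rx = 0
                n_fallbacks += 1
            confidences[(t, u)] = conf
            g.add_edge(t, u, weight=conf,
                       offset=(nominal[0] + ry, nominal[1] + rx), src=t)

    pos = {0: (0, 0)}
    if g.number_of_edges():
        tree = nx.maximum_spanning_tree(g, weight="weight")
        for u, v in nx.bfs_edges(tree, 0):
            dy, dx = tree.edges[u, v]["offset"]
            if tree.edges[u, v]["src"] != u:
                dy, dx = -dy, -dx
            pos[v] = (pos[u][0] + dy, pos[u][1] + dx)

    min_y = min(p[0] for p in pos.values())
    min_x = min(p[1] for p in pos.values())
    offsets = {t: (p[0] - min_y, p[1] - min_x) for t, p in pos.items()}
    canvas_shape = (
        max(o[0] for o in offsets.values()) + tile_shape[0],
        max(o[1] for o in offsets.values()) + tile_shape[1],
    )
    slayout = StitchLayout(
        offsets=offsets,
        canvas_shape=canvas_shape,
        tile_shape=tuple(tile_shape),
        edge_confidences=confidences,
        n_fallbacks=n_fallbacks,
    )
    return apply_stitch(tiles, slayout), slayout


def apply_stitch(tiles: Mapping[int, np.ndarray], slayout: StitchLayout) -> np.ndarray:
    """Assemble tiles onto a canvas with known offsets (max blending)."""
    canvas = np.zeros(slayout.canvas_shape, dtype=np.asarray(tiles[0]).dtype)
    for t, (oy, ox) in slayout.offsets.items():
        img = np.asarray(tiles[t])
        h, w = img.shape
        region = canvas[oy : oy + h, ox : ox + w]
        np.maximum(region, img, out=region)
    return canvas


# ---------------------------------------------------------------------------
# cross-round alignment


def shift_image(img: np.ndarray, dy: int, dx: int, fill=0) -> np.ndarray:
    """Translate image content by (dy, dx) with zero (``fill``) padding."""
    out = np.full_like(img, fill)
    h, w = img.shape
    ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else (slice(-dy, h), slice(0, h + dy))
    xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else (slice(-dx, w), slice(0, w + dx))
    out[yd, xd] = img[ys, xs]
    return out


def estimate_shift(ref: np.ndarray, img: np.ndarray,
                   search_margin_px: int = 8) -> tuple[int, int, float]:
    """Integer displacement of ``img`` relative to ``ref`` (same shape),
    found by scanning Pearson correlation within the search margin.
    Returns (dy, dx, confidence); degenerate images give (0, 0, 0.0).
    """
    ref, img = np.asarray(ref), np.asarray(img)
    if ref.shape != img.shape:
        raise ValueError("estimate_shift expects equal-shape images")
    if ref.std() == 0 or img.std() == 0:
        return 0, 0, 0.0
    m = int(search_margin_px)
    h, w = ref.shape
    best = (0, 0, -np.inf)
    candidates = sorted(
        ((dy, dx) for dy in range(-m, m + 1) for dx in range(-m, m + 1)),
        key=lambda r: (abs(r[0]) + abs(r[1]), r[0], r[1]),
    )
    for dy, dx in candidates:
        # img displaced by (dy, dx): img[y + dy, x + dx] == ref[y, x]
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        if (y1 - y0) * (x1 - x0) < 64:
            continue
        r = _pearson(ref[y0:y1, x0:x1], img[y0 + dy : y1 + dy, x0 + dx : x1 + dx])
        if r > best[2]:
            best = (dy, dx, r)
    if not np.isfinite(best[2]):
        return 0, 0, 0.0
    return best


def align_rounds(
    canvases_by_round: Sequence[Mapping[int, np.ndarray]],
    nuclear_channel: int,
    reference_round: int = 0,
    search_margin_px: int = 8,
) -> tuple[list[dict[int, np.ndarray]], dict[int, tuple[int, int]]]:
    """Register every round to a reference round by global translation.

    The shift is estimated on the nuclear channel (stable across rounds) and
    applied to all of that round's channels.  Canvases are first cropped to
    the common minimal shape.  Returns the aligned canvases and the detected
    per-round displacement (the reference round reports (0, 0)).
    """
    if not canvases_by_round:
        raise ValueError("need at least one round")
    hmin = min(np.asarray(d[nuclear_channel]).shape[0] for d in canvases_by_round)
    wmin = min(np.asarray(d[nuclear_channel]).shape[1] for d in canvases_by_round)
    cropped = [
        {c: np.asarray(img)[:hmin, :wmin] for c, img in d.items()}
        for d in canvases_by_round
    ]
    ref = cropped[reference_round][nuclear_channel]
    aligned: list[dict[int, np.ndarray]] = []
    shifts: dict[int, tuple[int, int]] = {}
    for r, channels in enumerate(cropped):
        if r == reference_round:
            shifts[r] = (0, 0)
            aligned.append(dict(channels))
            continue
        dy, dx, _conf = estimate_shift(ref, channels[nuclear_channel], search_margin_px)
        shifts[r] = (dy, dx)
        aligned.append({c: shift_image(img, -dy, -dx) for c, img in channels.items()})
    return aligned, shifts


def downscale(img: np.ndarray, factor: int, reduce: str = "mean") -> np.ndarray:
    """Block-downsample an image by an integer factor (emulates imaging the
    same field at a lower magnification).  ``reduce`` is "mean" or "max"."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    img = np.asarray(img)
    h, w = (img.shape[0] // factor) * factor, (img.shape[1] // factor) * factor
    blocks = img[:h, :w].reshape(h // factor, factor, w // factor, factor)
    if reduce == "mean":
        return blocks.mean(axis=(1, 3))
    if reduce == "max":
        return blocks.max(axis=(1, 3))
    raise ValueError("reduce must be 'mean' or 'max'")
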