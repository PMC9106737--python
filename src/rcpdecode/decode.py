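"""Gene calling: sequential lookup and combinatorial cross-cycle decoding.

Sequential readout assigns one gene per (round, channel) — a direct lookup.
Combinatorial readout reads the same RCP in a different channel each cycle;
decoding must link each first-cycle spot to its nearest neighbour in the
next cycle (and so on), producing a candidate barcode whose confidence is

    Q = prod_{i=1}^{n-1} ( q_i * q_{i+1} - k * d_{i(i+1)} )

with q_i the per-cycle channel-purity qualities, d_{i(i+1)} the Euclidean
pixel distance between the linked spots of consecutive cycles, and k a
tunable distance penalty (per pixel).  For the two-cycle case this is
exactly q1*q2 - k*d12.  Candidates are kept only when Q > 0, surviving
barcodes are looked up in the codebook, and when two candidates claim the
same spot only the higher-Q one survives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .simio import Codebook

__all__ = [
    "BarcodeCandidate",
    "assign_sequential",
    "link_cycles",
    "score_barcode",
    "filter_and_call",
    "efficiency_slope",
]


@dataclass
class BarcodeCandidate:
    """A cross-cycle chain of spots forming one possible barcode.

    ``spot_ids`` are the member spot ids, one per cycle; ``distances`` holds
    the n-1 consecutive inter-cycle distances in pixels.  ``y``/``x`` anchor
    the candidate at its first-cycle spot.
    """

    spot_ids: tuple[int, ...]
    channels: tuple[int, ...]
    qualities: tuple[float, ...]
    distances: tuple[float, ...]
    y: float
    x: float
    Q: float | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        n = len(self.spot_ids)
        if n < 2:
            raise ValueError("a barcode needs at least 2 cycles")
        if len(self.channels) != n or len(self.qualities) != n:
            raise ValueError("channels/qualities must have one entry per cycle")
        if len(self.distances) != n - 1:
            raise ValueError("need n-1 inter-cycle distances")
        if any(d < 0 for d in self.distances):
            raise ValueError("distances must be nonnegative")

    @property
    def total_distance(self) -> float:
        return float(sum(self.distances))


def assign_sequential(spots: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    """Label each spot with the gene assigned to its (round, channel).

    Spots at (round, channel) slots absent from the codebook are labelled
    ``unassigned`` and retained.
    """
    if codebook.mode != "sequential":
        raise ValueError("assign_sequential needs a sequential codebook")
    lookup = codebook.lookup()
    out = spots.copy()
    out["gene"] = [
        lookup.get((int(r), int(c)), "unassigned")
        for r, c in zip(out["round"], out["channel"])
    ]
    return out


def link_cycles(
    per_cycle_spots: Sequence[pd.DataFrame], max_radius_px: float
) -> list[BarcodeCandidate]:
    """Chain spots across cycles by nearest-neighbour association.

    Each first-cycle spot is associated with its closest second-cycle spot
    within ``max_radius_px``; chains extend greedily cycle-to-cycle from the
    previous member's position.  A first-cycle spot with no neighbour in
    range yields no candidate; a later-cycle spot may be claimed by several
    chains at this stage (conflicts are resolved later by Q ranking).
    Qualities are taken from each table's ``quality`` column.
    """
    if len(per_cycle_spots) < 2:
        raise ValueError("combinatorial linking needs at least 2 cycles")
    trees = []
    for cyc, df in enumerate(per_cycle_spots):
        pts = df[["y", "x"]].to_numpy(dtype=np.float64)
        trees.append(cKDTree(pts) if len(pts) else None)

    candidates: list[BarcodeCandidate] = []
    first = per_cycle_spots[0]
    for row in first.itertuples(index=False):
        ids = [int(row.spot_id)]
        channels = [int(row.channel)]
        qualities = [float(row.quality)]
        distances: list[float] = []
        pos = (float(row.y), float(row.x))
        ok = True
        for cyc in range(1, len(per_cycle_spots)):
            tree = trees[cyc]
            if tree is None:
                ok = False
                break
            d, j = tree.query(pos, k=1, distance_upper_bound=max_radius_px)
            if not math.isfinite(d):
                ok = False
                break
            nxt = per_cycle_spots[cyc].iloc[int(j)]
            ids.append(int(nxt["spot_id"]))
            channels.append(int(nxt["channel"]))
            qualities.append(float(nxt["quality"]))
            distances.append(float(d))
            pos = (float(nxt["y"]), float(nxt["x"]))
        if ok:
            candidates.append(
                BarcodeCandidate(
                    spot_ids=tuple(ids),
                    channels=tuple(channels),
                    qualities=tuple(qualities),
                    distances=tuple(distances),
                    y=float(row.y),
                    x=float(row.x),
                )
            )
    return candidates


def score_barcode(candidate: BarcodeCandidate, k: float) -> float:
    """Combined barcode confidence Q.

    Q is the product over consecutive cycle pairs of the pair's quality
    product minus the distance penalty: prod_i (q_i q_{i+1} - k d_{i(i+1)}).
    For two cycles this reduces to q1*q2 - k*d12.  Strictly decreasing in
    every distance and in k while the bracketed terms stay positive.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    q = candidate.qualities
    d = candidate.distances
    terms = [q[i] * q[i + 1] - k * d[i] for i in range(len(d))]
    return float(np.prod(terms))


def filter_and_call(
    candidates: Sequence[BarcodeCandidate],
    codebook: Codebook,
) -> tuple[pd.DataFrame, dict]:
    """Apply the Q > 0 filter, resolve conflicts and look up genes.

    Candidates must already carry Q.  Candidates with Q <= 0 are dropped;
    among survivors sharing a member spot only the highest-Q one is kept
    (ties: smaller total distance, then input order).  Surviving barcodes
    are looked up in the codebook — channel sequences with no codebook entry
    are labelled ``invalid_barcode``, dropped from the expression path and
    counted in the returned diagnostics.
    """
    if codebook.mode != "combinatorial":
        raise ValueError("filter_and_call needs a combinatorial codebook")
    for cand in candidates:
        if cand.Q is None:
            raise ValueError("candidates must be scored before filtering")
    scored = [c for c in candidates if c.Q > 0]
    n_dropped_q = len(candidates) - len(scored)

    order = sorted(
        range(len(scored)),
        key=lambda i: (-scored[i].Q, scored[i].total_distance, i),
    )
    used: set[tuple[int, int]] = set()
    kept: list[BarcodeCandidate] = []
    for i in order:
        cand = scored[i]
        keys = {(cyc, sid) for cyc, sid in enumerate(cand.spot_ids)}
        if keys & used:
            continue
        used |= keys
        kept.append(cand)
    kept.sort(key=lambda c: (c.y, c.x))

    lookup = codebook.lookup()
    rows = []
    n_invalid = 0
    for cand in kept:
        gene = lookup.get(cand.channels)
        if gene is None:
            cand.gene = "invalid_barcode"
            n_invalid += 1
            continue
        cand.gene = gene
        rows.append(
            (cand.y, cand.x, gene, cand.Q,
             "-".join(str(c) for c in cand.channels),
             min(cand.qualities), cand.total_distance)
        )
    decoded = pd.DataFrame(
        rows, columns=["y", "x", "gene", "Q", "barcode", "min_quality",
                       "total_distance"]
    )
    diagnostics = {
        "n_candidates": len(candidates),
        "n_dropped_q": n_dropped_q,
        "n_conflict_dropped": len(scored) - len(kept),
        "n_invalid_barcode": n_invalid,
        "n_called": len(decoded),
    }
    return decoded, diagnostics


def efficiency_slope(
    counts_a: np.ndarray | pd.DataFrame, counts_b: np.ndarray | pd.DataFrame
) -> tuple[float, float]:
    """Through-origin regression slope of condition-B totals on condition-A
    totals over matched (ROI, gene) pairs, plus the Pearson correlation.

    This is the detection-efficiency comparison: summed spot counts per ROI
    and gene in two conditions, slope = sum(a*b) / sum(a*a).
    """
    a = np.asarray(counts_a, dtype=np.float64).ravel()
    b = np.asarray(counts_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("conditions must provide matched (ROI, gene) totals")
    denom = float(np.dot(a, a))
    if denom == 0.0:
        raise ValueError("condition-A totals are all zero; slope undefined")
    slope = float(np.dot(a, b)) / denom
    if a.std() == 0 or b.std() == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return slope, r
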