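"""Background removal, spot calling and per-spot quality scoring.

Signals are rolling circle products: bright, roughly diffraction-limited
blobs on a slowly varying background.  The background is removed with a
white top-hat (image minus its morphological opening with a disk), then
spots are called as 8-connected components above a manually chosen intensity
threshold, with a size gate.  Each spot gets a channel-purity quality

    q = I_detected / max(sum of other signal-channel intensities, floor)

measured at the spot's centroid pixel on the top-hat-filtered canvases of
its round, excluding the nuclear channel.  A spectrally clean spot has high
q; a spot bleeding into other channels (or a noise pick-up) has low q.  The
floor (default 1 intensity unit) guards the division when all other
channels are dark; away from the floor q is invariant to rescaling all
intensities.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from skimage import measure, morphology

from .simio import AcquisitionLayout

__all__ = [
    "tophat_filter",
    "detect_spots",
    "spot_quality",
    "measure_quality",
    "measure_snr",
    "SNR_CAP",
]

SNR_CAP = 1.0e4  # reported SNR for spots whose local background has zero spread


def tophat_filter(image: np.ndarray, radius_px: int) -> np.ndarray:
    """White top-hat with a disk structuring element: image minus opening."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    return morphology.white_tophat(np.asarray(image), morphology.disk(radius_px))


def detect_spots(
    image: np.ndarray,
    intensity_threshold: float,
    size_min_px: int,
    size_max_px: int,
    round_index: int = 0,
    channel: int = 0,
) -> pd.DataFrame:
    """Call spots on one (round, channel) top-hat-filtered canvas.

    Spots are 8-connected components of pixels >= the intensity threshold;
    components with area outside [size_min_px, size_max_px] are discarded.
    The centroid is the intensity-weighted mean position and the reported
    intensity is the component maximum.
    """
    if intensity_threshold <= 0 or size_min_px <= 0:
        raise ValueError("thresholds must be positive")
    if size_min_px > size_max_px:
        raise ValueError("size_min_px must be <= size_max_px")
    image = np.asarray(image)
    labels = measure.label(image >= intensity_threshold, connectivity=2)
    rows = []
    for prop in measure.regionprops(labels, intensity_image=image):
        if not (size_min_px <= prop.area <= size_max_px):
            continue
        cy, cx = prop.centroid_weighted
        rows.append((round_index, channel, cy, cx, float(prop.intensity_max),
                     int(prop.area)))
    df = pd.DataFrame(
        rows, columns=["round", "channel", "y", "x", "intensity", "area"]
    ).astype(
        {"round": np.int64, "channel": np.int64, "y": np.float64,
         "x": np.float64, "intensity": np.float64, "area": np.int64}
    )
    df.insert(0, "spot_id", np.arange(len(df), dtype=np.int64))
    return df


def spot_quality(
    detected_channel: int,
    intensities: Mapping[int, float],
    floor: float = 1.0,
) -> float:
    """Channel-purity quality of one spot.

    ``intensities`` maps each signal (non-nuclear) channel of the spot's
    round to the top-hat intensity at the spot's centroid pixel; the nuclear
    channel must not be included.  q = detected / max(sum of others, floor).
    """
    if detected_channel not in intensities:
        raise KeyError(
            f"detected channel {detected_channel} missing from intensity vector"
        )
    others = sum(v for c, v in intensities.items() if c != detected_channel)
    return float(intensities[detected_channel]) / max(float(others), float(floor))


def measure_quality(
    spots: pd.DataFrame,
    filtered_canvases: Mapping[tuple[int, int], np.ndarray],
    layout: AcquisitionLayout,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Attach the q score to every spot of a multi-channel spot table.

    ``filtered_canvases`` maps (round, channel) to the top-hat canvases the
    spots were detected on; all signal channels of each represented round
    must be present.
    """
    spots = spots.copy()
    qualities = np.full(len(spots), np.nan)
    for i, s in enumerate(spots.itertuples(index=False)):
        rnd = int(s.round)
        yi = int(round(s.y))
        xi = int(round(s.x))
        vec = {}
        for c in layout.signal_channels:
            canvas = filtered_canvases[(rnd, c)]
            h, w = canvas.shape
            vec[c] = float(canvas[min(max(yi, 0), h - 1), min(max(xi, 0), w - 1)])
        qualities[i] = spot_quality(int(s.channel), vec, floor)
    spots["quality"] = qualities
    return spots


def measure_snr(
    spots: pd.DataFrame,
    raw_canvas: np.ndarray,
    structuring_radius_px: int = 3,
    foreground_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-spot signal-to-noise ratio on the raw (pre-top-hat) canvas.

    SNR = (peak - median of local background) / robust sd of local
    background, the background taken from an annulus of inner radius
    2x and outer radius 4x the structuring radius around the spot centroid.
    Pixels under ``foreground_mask`` (e.g. all detected spots) are excluded
    from the annulus.  Spots whose annulus is fully occluded get NaN; a
    zero-spread background reports the documented cap ``SNR_CAP``.

    Returns (per-spot table with an ``snr`` column, per-channel median
    summary).
    """
    raw = np.asarray(raw_canvas, dtype=np.float64)
    h, w = raw.shape
    r_in, r_out = 2 * structuring_radius_px, 4 * structuring_radius_px
    yy, xx = np.mgrid[-r_out : r_out + 1, -r_out : r_out + 1]
    rr = np.sqrt(yy**2 + xx**2)
    ring = (rr >= r_in) & (rr <= r_out)
    out = spots.copy()
    snrs = np.full(len(spots), np.nan)
    for i, s in enumerate(spots.itertuples(index=False)):
        yi, xi = int(round(s.y)), int(round(s.x))
        y0, y1 = yi - r_out, yi + r_out + 1
        x0, x1 = xi - r_out, xi + r_out + 1
        cy0, cy1 = max(0, y0), min(h, y1)
        cx0, cx1 = max(0, x0), min(w, x1)
        sel = ring[cy0 - y0 : cy1 - y0, cx0 - x0 : cx1 - x0].copy()
        patch = raw[cy0:cy1, cx0:cx1]
        if foreground_mask is not None:
            sel &= ~foreground_mask[cy0:cy1, cx0:cx1]
        bg = patch[sel]
        if bg.size < 10:
            continue  # annulus occluded: SNR stays NaN
        med = float(np.median(bg))
        mad = float(np.median(np.abs(bg - med)))
        sd = 1.4826 * mad
        peak = float(raw[min(max(yi, 0), h - 1), min(max(xi, 0), w - 1)])
        snrs[i] = min((peak - med) / sd, SNR_CAP) if sd > 0 else SNR_CAP
    out["snr"] = snrs
    if len(out):
        summary = (
            out.groupby("channel")["snr"].median().rename("median_snr").reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["channel", "median_snr"])
    return out, summary
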