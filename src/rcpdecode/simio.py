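"""Readers, writers and shared conventions for the pipeline's file formats.

Coordinate convention (used by every module): pixel coordinates are 0-based
``(y, x)`` = (row, col) with the origin at the top-left of the *stitched*
canvas; tile rectangles are half-open ``[y0, y1) x [x0, x1)``.  Images are
16-bit unsigned TIFF; 8-bit input is accepted and upcast without rescaling.

On disk a tiled acquisition is a directory of multi-page TIFF z-stacks named
``t{tile:03d}_r{round}_c{channel}.tif`` with tiles numbered row-major on the
stage grid.  Spot tables are plain CSV, expression matrices are MatrixMarket
with ``cells.csv``/``genes.csv`` sidecars (cells are rows).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import tifffile
import yaml

__all__ = [
    "AcquisitionLayout",
    "Codebook",
    "RunConfig",
    "TileSet",
    "SPOT_COLUMNS",
    "tile_filename",
    "read_tile_stack",
    "write_tileset",
    "write_spot_table",
    "read_spot_table",
    "write_expression",
    "read_expression",
    "write_canvases",
    "read_canvases",
    "write_label_mask",
    "read_label_mask",
]


# ---------------------------------------------------------------------------
# acquisition geometry


@dataclass(frozen=True)
class AcquisitionLayout:
    """Geometry of a tiled, multi-round, multi-channel acquisition.

    ``overlap_fraction`` is the fraction of each tile dimension shared with
    the adjacent tile (default 0.10, i.e. 10% overlap).  Exactly one channel
    is the nuclear (DAPI) channel; the remaining channels carry RCP signal.
    ``z_steps`` is the number of planes per z-stack (the acquisition covers
    the tissue depth; planes are collapsed by maximum projection downstream).
    """

    grid_rows: int = 1
    grid_cols: int = 1
    tile_height_px: int = 256
    tile_width_px: int = 256
    overlap_fraction: float = 0.10
    n_rounds: int = 1
    channel_names: tuple[str, ...] = ("DAPI", "AF488", "Cy3", "Cy5", "AF750")
    nuclear_channel: int = 0
    z_steps: int = 1

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one tile along each axis")
        if self.tile_height_px < 1 or self.tile_width_px < 1:
            raise ValueError("tile dimensions must be positive")
        if not (0.0 <= self.overlap_fraction < 0.5):
            raise ValueError("overlap_fraction must lie in [0, 0.5)")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.z_steps < 1:
            raise ValueError("z_steps must be >= 1")
        if len(self.channel_names) < 2:
            raise ValueError("need a nuclear channel plus at least one signal channel")
        if not (0 <= self.nuclear_channel < len(self.channel_names)):
            raise ValueError("nuclear_channel out of range")
        if self.grid_rows > 1 and self.overlap_py < 1:
            raise ValueError("vertical overlap must be >= 1 px for a multi-row grid")
        if self.grid_cols > 1 and self.overlap_px < 1:
            raise ValueError("horizontal overlap must be >= 1 px for a multi-column grid")

    # -- derived geometry ---------------------------------------------------

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_tiles(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def signal_channels(self) -> tuple[int, ...]:
        return tuple(c for c in range(self.n_channels) if c != self.nuclear_channel)

    @property
    def overlap_py(self) -> int:
        return int(round(self.overlap_fraction * self.tile_height_px))

    @property
    def overlap_px(self) -> int:
        return int(round(self.overlap_fraction * self.tile_width_px))

    @property
    def step_y(self) -> int:
        return self.tile_height_px - self.overlap_py

    @property
    def step_x(self) -> int:
        return self.tile_width_px - self.overlap_px

    @property
    def canvas_shape(self) -> tuple[int, int]:
        """Stitched-canvas shape implied by nominal (jitter-free) offsets."""
        h = self.tile_height_px + (self.grid_rows - 1) * self.step_y
        w = self.tile_width_px + (self.grid_cols - 1) * self.step_x
        return h, w

    def tile_index(self, row: int, col: int) -> int:
        return row * self.grid_cols + col

    def tile_rowcol(self, tile: int) -> tuple[int, int]:
        return divmod(tile, self.grid_cols)

    def nominal_offset(self, tile: int) -> tuple[int, int]:
        """Nominal canvas position (y, x) of a tile's top-left corner."""
        r, c = self.tile_rowcol(tile)
        return r * self.step_y, c * self.step_x

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["channel_names"] = list(doc["channel_names"])
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_dict(cls, doc: Mapping) -> "AcquisitionLayout":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(doc) - known)
        if unknown:
            raise ValueError("unknown layout keys: " + ", ".join(map(repr, unknown)))
        doc = dict(doc)
        if "channel_names" in doc:
            doc["channel_names"] = tuple(doc["channel_names"])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AcquisitionLayout":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# codebook


@dataclass
class Codebook:
    """Gene-to-readout assignment.

    * sequential mode: each gene maps to one ``(round, channel)`` pair — gene
      identity is a direct lookup, one gene per round and channel.
    * combinatorial mode: each gene maps to a channel sequence of length
      ``n_cycles`` (>= 2) — the same RCP is read out in a different channel
      each cycle and the sequence is the barcode.

    ``gene_tags`` optionally carries the 20-character unique ID sequence
    assigned to each gene's probe backbone.
    """

    mode: str
    entries: dict[str, tuple[int, ...]]
    gene_tags: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("sequential", "combinatorial"):
            raise ValueError(f"unknown codebook mode {self.mode!r}")
        self.entries = {g: tuple(int(v) for v in a) for g, a in self.entries.items()}
        if not self.entries:
            raise ValueError("codebook has no entries")
        assignments = list(self.entries.values())
        if len(set(assignments)) != len(assignments):
            raise ValueError("codebook assignments must be unique across genes")
        if self.mode == "sequential":
            if any(len(a) != 2 for a in assignments):
                raise ValueError("sequential assignments must be (round, channel) pairs")
        else:
            lengths = {len(a) for a in assignments}
            if len(lengths) != 1:
                raise ValueError("combinatorial barcodes must all have the same length")
            if lengths.pop() < 2:
                raise ValueError("combinatorial barcodes need n_cycles >= 2")
        if self.gene_tags is not None:
            for g, tag in self.gene_tags.items():
                if len(tag) != 20:
                    raise ValueError(f"gene ID tag for {g!r} must be 20 characters")

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    @property
    def n_cycles(self) -> int:
        if self.mode != "combinatorial":
            raise ValueError("n_cycles is defined for combinatorial codebooks only")
        return len(next(iter(self.entries.values())))

    def lookup(self) -> dict[tuple[int, ...], str]:
        """Inverse map: assignment tuple -> gene."""
        return {a: g for g, a in self.entries.items()}

    def validate_against(self, layout: AcquisitionLayout) -> None:
        """Check channel/round indices against an acquisition layout."""
        signal = set(layout.signal_channels)
        for gene, a in self.entries.items():
            if self.mode == "sequential":
                rnd, ch = a
                if not (0 <= rnd < layout.n_rounds):
                    raise ValueError(f"{gene}: round {rnd} outside layout")
                channels = (ch,)
            else:
                if len(a) > layout.n_rounds:
                    raise ValueError(f"{gene}: barcode longer than n_rounds")
                channels = a
            for ch in channels:
                if ch not in signal:
                    raise ValueError(
                        f"{gene}: channel {ch} is not a signal (non-nuclear) channel"
                    )

    def to_yaml(self, path: str | Path) -> None:
        doc = {"mode": self.mode, "genes": {g: list(a) for g, a in self.entries.items()}}
        if self.gene_tags is not None:
            doc["gene_tags"] = dict(self.gene_tags)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Codebook":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            mode=doc["mode"],
            entries={g: tuple(a) for g, a in doc["genes"].items()},
            gene_tags=doc.get("gene_tags"),
        )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """All downstream tunables as a flat key/value document.

    Every key has a default; unknown keys in a config file are rejected (all
    offenders reported at once).  ``detect_threshold`` may be a single number
    applied to every signal channel or a per-signal-channel list — the
    thresholds are manual settings, chosen per channel by inspection.
    """

    seed: int = 0
    # spot calling
    tophat_radius_px: int = 3
    detect_smooth_sigma_px: float = 0.0  # matched pre-smoothing; 0 disables
    detect_threshold: float | tuple[float, ...] = 6000.0
    size_min_px: int = 4
    size_max_px: int = 200
    quality_floor: float = 1.0
    # registration
    stitch_margin_px: int = 5
    align_margin_px: int = 8
    min_stitch_confidence: float = 0.3
    # combinatorial decoding
    link_radius_px: float = 5.0
    k: float = 0.2
    # segmentation
    dapi_threshold: float = 10000.0
    min_nucleus_px: int = 50
    nucleus_peak_min_distance_px: int = 6
    max_expansion_px: int = 15
    # density quantification (low-magnification mode)
    density_threshold: float = 2000.0
    # expression analysis
    min_counts_per_cell: int = 5
    min_cells_per_gene: int = 2
    normalize_target: float = 0.0  # 0 -> median of per-cell totals
    n_neighbors: int = 15
    resolution: float = 1.0
    pca_components: int = 20

    def __post_init__(self) -> None:
        if isinstance(self.detect_threshold, (list, tuple)):
            self.detect_threshold = tuple(float(v) for v in self.detect_threshold)

    def threshold_for(self, signal_channel_pos: int) -> float:
        """Detection threshold for the i-th signal channel (0-based among
        non-nuclear channels)."""
        if isinstance(self.detect_threshold, tuple):
            return self.detect_threshold[signal_channel_pos]
        return float(self.detect_threshold)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["detect_threshold"], tuple):
            d["detect_threshold"] = list(d["detect_threshold"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(doc) - known)
        if unknown:
            raise ValueError(
                "unknown run-config keys: " + ", ".join(repr(k) for k in unknown)
            )
        return cls(**dict(doc))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ValueError("run config must be a flat key/value mapping")
        return cls.from_dict(doc)


# ---------------------------------------------------------------------------
# tile stacks


@dataclass
class TileSet:
    """Raw acquisition: one z-stack per (tile, round, channel) plus layout."""

    layout: AcquisitionLayout
    stacks: dict[tuple[int, int, int], np.ndarray]

    def stack(self, tile: int, rnd: int, channel: int) -> np.ndarray:
        return self.stacks[(tile, rnd, channel)]


def tile_filename(tile: int, rnd: int, channel: int) -> str:
    return f"t{tile:03d}_r{rnd}_c{channel}.tif"


def _as_uint16(arr: np.ndarray, name: str) -> np.ndarray:
    if arr.dtype == np.uint16:
        return arr
    if arr.dtype == np.uint8:
        return arr.astype(np.uint16)
    raise ValueError(f"{name}: expected 8- or 16-bit unsigned pixels, got {arr.dtype}")


def read_tile_stack(path: str | Path, layout: AcquisitionLayout) -> TileSet:
    """Read a directory of TIFF z-stacks into a :class:`TileSet`.

    Files must follow ``t{tile:03d}_r{round}_c{channel}.tif`` and match the
    layout exactly; a missing or misshapen file is a hard error naming the
    offending (tile, round, channel), as is any extra stack file.
    """
    path = Path(path)
    expected = {
        (t, r, c): tile_filename(t, r, c)
        for t in range(layout.n_tiles)
        for r in range(layout.n_rounds)
        for c in range(layout.n_channels)
    }
    present = {p.name for p in path.glob("t*_r*_c*.tif")}
    extra = sorted(present - set(expected.values()))
    if extra:
        raise ValueError(f"unexpected tile files not in layout: {extra}")
    stacks: dict[tuple[int, int, int], np.ndarray] = {}
    shape = (layout.z_steps, layout.tile_height_px, layout.tile_width_px)
    for key, name in expected.items():
        fp = path / name
        if not fp.exists():
            raise FileNotFoundError(
                f"missing tile stack {name} for (tile, round, channel)={key}"
            )
        arr = tifffile.imread(fp)
        if arr.ndim == 2:  # single-plane stacks come back 2-D
            arr = arr[None]
        if arr.shape != shape:
            raise ValueError(
                f"{name}: shape {arr.shape} does not match layout {shape} "
                f"for (tile, round, channel)={key}"
            )
        stacks[key] = _as_uint16(arr, name)
    return TileSet(layout=layout, stacks=stacks)


def write_tileset(tileset: TileSet, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for (t, r, c), arr in tileset.stacks.items():
        tifffile.imwrite(
            path / tile_filename(t, r, c),
            _as_uint16(arr, "stack"),
            photometric="minisblack",
        )


# ---------------------------------------------------------------------------
# spot tables

SPOT_COLUMNS = (
    "spot_id",
    "round",
    "channel",
    "y",
    "x",
    "intensity",
    "area",
    "quality",
    "gene",
    "cell_id",
    "Q",
)

_SPOT_DTYPES = {
    "spot_id": np.int64,
    "round": np.int64,
    "channel": np.int64,
    "y": np.float64,
    "x": np.float64,
    "intensity": np.float64,
    "area": np.int64,
    "quality": np.float64,
    "gene": object,
    "cell_id": np.int64,
    "Q": np.float64,
}


def normalize_spot_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fill missing schema columns with defaults and order columns."""
    df = df.copy()
    defaults = {
        "spot_id": None,
        "quality": np.nan,
        "gene": "",
        "cell_id": -1,
        "Q": np.nan,
    }
    if "spot_id" not in df.columns:
        df["spot_id"] = np.arange(len(df), dtype=np.int64)
    for col, val in defaults.items():
        if col not in df.columns and val is not None:
            df[col] = val
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table missing columns: {missing}")
    df = df.loc[:, list(SPOT_COLUMNS)]
    for col, dt in _SPOT_DTYPES.items():
        if dt is not object:
            df[col] = df[col].astype(dt)
        else:
            df[col] = df[col].astype(str).where(df[col].notna(), "")
    return df.reset_index(drop=True)


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    """Write a spot table as CSV (floats at full round-trip precision)."""
    # shortest round-trip repr: read_spot_table recovers floats bit-exactly
    normalize_spot_table(spots).to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )


def read_spot_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            dtype=_SPOT_DTYPES,
            keep_default_na=False,
            na_values=[""],
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed spot table {path}: {exc}") from exc
    if tuple(df.columns) != SPOT_COLUMNS:
        raise ValueError(
            f"malformed spot table {path} (line 1): header {list(df.columns)} "
            f"!= {list(SPOT_COLUMNS)}"
        )
    df["gene"] = df["gene"].fillna("").astype(str)
    return normalize_spot_table(df)


# ---------------------------------------------------------------------------
# expression matrices


def write_expression(quant, path: str | Path) -> None:
    """Write a cell-by-gene quantification as MatrixMarket plus sidecars.

    Produces ``matrix.mtx`` (cells are rows), ``cells.csv`` with per-cell
    centroid and area, and ``genes.csv``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = scipy.sparse.csr_matrix(np.asarray(quant.matrix))
    scipy.io.mmwrite(str(path / "matrix.mtx"), mat)
    meta = quant.cell_meta.copy()
    meta.insert(0, "cell_id", np.asarray(quant.cell_ids, dtype=np.int64))
    meta.to_csv(path / "cells.csv", index=False)
    pd.DataFrame({"gene": list(quant.genes)}).to_csv(path / "genes.csv", index=False)


def read_expression(path: str | Path):
    """Read back what :func:`write_expression` wrote.

    Returns ``(matrix, cell_ids, genes, cell_meta)``; the matrix is dense.
    """
    path = Path(path)
    mat = scipy.io.mmread(str(path / "matrix.mtx"))
    mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    cells = pd.read_csv(path / "cells.csv")
    genes = pd.read_csv(path / "genes.csv")["gene"].astype(str).tolist()
    cell_ids = cells["cell_id"].to_numpy(dtype=np.int64)
    meta = cells.drop(columns=["cell_id"])
    return mat, cell_ids, genes, meta


# ---------------------------------------------------------------------------
# stitched canvases and label masks


def write_canvases(canvases: Mapping[tuple[int, int], np.ndarray], path: str | Path) -> None:
    """Write per-(round, channel) stitched canvases as ``r{r}_c{c}.tif``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for (r, c), img in canvases.items():
        tifffile.imwrite(path / f"r{r}_c{c}.tif", np.asarray(img))


def read_canvases(path: str | Path) -> dict[tuple[int, int], np.ndarray]:
    path = Path(path)
    out: dict[tuple[int, int], np.ndarray] = {}
    for fp in sorted(path.glob("r*_c*.tif")):
        stem = fp.stem  # r{r}_c{c}
        r_part, c_part = stem.split("_")
        out[(int(r_part[1:]), int(c_part[1:]))] = tifffile.imread(fp)
    if not out:
        raise FileNotFoundError(f"no canvas TIFFs (r*_c*.tif) under {path}")
    return out


def write_label_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask)
    if mask.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label mask has more than 65535 labels")
    tifffile.imwrite(path, mask.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int64)
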